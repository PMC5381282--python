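"""Subcluster consensus patterns and the EcoRI de novo estimate.

For Categories E and G, sites where both subclusters are internally
uniform are tabulated as (Bhutanese consensus, subcluster-1, subcluster-2)
triples.  The directional totals compare heterozygosity retention between
the subclusters.  The Category-G event count also feeds the de novo
estimator: if those events were mutations falling uniformly over the
36-bp flank of the restriction site, the 6-bp recognition site itself
suffers count/6 mutations — enzyme-site loss masquerading as homozygosity.
"""

from limerad import (
    classify_matrix,
    default_partition,
    ecori_denovo_estimate,
    paperlike_params,
    simulate,
    subpattern_table,
)

partition = default_partition()
result = simulate(paperlike_params(n_sites=10_000, seed=42))
report, filtered = classify_matrix(result.matrix, partition)

for category in ("E", "G"):
    tab = subpattern_table(filtered, partition, report, category)
    print(f"Category {category}: {report.counts[category]} sites, "
          f"{tab.remainder_count} with a non-uniform subcluster")
    print(f"  subcluster-1 het / subcluster-2 hom: {tab.sub1_het_sub2_hom}")
    print(f"  subcluster-1 hom / subcluster-2 het: {tab.sub1_hom_sub2_het}")

g_count = report.counts["G"]
print(f"\nEcoRI-site de novo estimate from {g_count} Category-G events: "
      f"{ecori_denovo_estimate(g_count)}")
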