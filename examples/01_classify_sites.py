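"""Classify a synthetic clonal panel's sites into Categories A-L.

Generates a paperlike eight-accession genotype matrix, filters it to
genotypable sites, and tallies the site categories over the default
two-cluster partition.  Categories C and D (het in one cluster, hom in
the other) are the classic loss-of-heterozygosity signature separating
the two clusters; Category A is the founder heterozygosity both clusters
still share.
"""

from limerad import classify_matrix, default_partition, paperlike_params, simulate

result = simulate(paperlike_params(n_sites=10_000, seed=42))
partition = default_partition()
report, filtered = classify_matrix(result.matrix, partition)

print(f"simulated sites:      {report.n_sites_total}")
print(f"genotypable sites:    {report.n_sites_genotypable}")
print("category counts (sum equals the genotypable total):")
for label, count in report.counts.items():
    if count:
        print(f"  {label}: {count}")
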