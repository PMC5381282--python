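"""Per-accession heterozygosity and within-category genotype matches.

The heterozygous-call count per accession is a floor on its true
heterozygosity (only genotyped sites count); the frequency scales it to
all analyzed bases (loci x read length).  The match matrix inside
Category E shows which accessions of the subclustered cluster share
genotypes — high off-diagonal counts inside a subcluster are what makes
the subcluster visible.
"""

from limerad import (
    classify_matrix,
    default_partition,
    het_stats,
    pairwise_matches,
    paperlike_params,
    simulate,
    total_bases,
)

partition = default_partition()
result = simulate(paperlike_params(n_sites=10_000, seed=42))
report, filtered = classify_matrix(result.matrix, partition)

tb = total_bases(n_loci=10_000, read_length=41)
print("heterozygosity per accession (count over genotypable sites, % of bases):")
print(het_stats(filtered, tb)[["het_sites", "het_pct_2dp"]])

e_sites = [i for i, lab in enumerate(report.per_site) if lab == "E"]
indo = partition.members("Indonesian")
print(f"\ngenotype matches within the Indonesian cluster over {len(e_sites)}"
      " Category-E sites:")
print(pairwise_matches(filtered, e_sites, indo))
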