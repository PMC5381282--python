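"""Plant a loss-of-heterozygosity rate and recover it from the categories.

With LOH confined to the Indonesian-ancestor branch, every founder-het
site ends up Category A (untouched) or Category C (resolved in the whole
Indonesian cluster), so #C / (#A + #C) estimates the planted per-site
rate.
"""

import numpy as np

from limerad import classify_matrix, default_partition, estimate_rates, simulate
from limerad.simulate import SimParams, default_lineage_tree

rate = 0.2
params = SimParams(
    n_sites=20_000,
    p_het=0.5,
    branches=default_lineage_tree(loh={"indonesian_ancestor": rate}),
    seed=7,
)
result = simulate(params)
report, _ = classify_matrix(result.matrix, default_partition())
est = estimate_rates(result, report)

n = report.counts["A"] + report.counts["C"]
se = np.sqrt(rate * (1 - rate) / n)
print(f"planted LOH rate on the Indonesian-ancestor branch: {rate}")
print(f"recovered  #C/(#A+#C) = {est['r_loh_cluster2']:.4f}"
      f"  (binomial SE {se:.4f}, n = {n})")
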