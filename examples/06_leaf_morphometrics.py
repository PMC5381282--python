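"""Leaf ellipse areas and the wing index.

Leaf blades and wings are treated as ellipses (area = width/2 x length/2
x pi); the wing index — wing area as a percent of blade area — is the
trait that separates small-winged from large-winged lime accessions.
The synthetic five-leaf set below mimics a small-winged accession.
"""

import pandas as pd

from limerad import group_summary, wing_index

# printed mean areas of a small-winged accession: 2.01 pi (wing) over
# 335.7 pi (blade) -> index 0.60
print(f"wing index from mean areas 2.01pi / 335.7pi: "
      f"{wing_index(2.01, 335.7):.2f}")

leaves = pd.DataFrame(
    {
        "accession": ["Bhutan-like"] * 5,
        "blade_length_mm": [51.1, 49.0, 52.5, 50.2, 53.0],
        "blade_width_mm": [26.2, 25.5, 27.0, 25.9, 26.8],
        "wing_length_mm": [5.7, 5.4, 6.0, 5.5, 5.9],
        "wing_width_mm": [1.4, 1.3, 1.5, 1.4, 1.5],
    }
)
summary = group_summary(leaves)
print("\nper-accession summary (areas in pi mm^2, index = mean of per-leaf ratios):")
print(summary.round(2))
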