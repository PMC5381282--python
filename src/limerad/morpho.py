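"""Leaf morphometrics: ellipse areas and the wing index.

Leaf blades and leaf wings are approximated as ellipses from their
length and width (``area = width/2 * length/2 * pi``), and the wing
index — the discriminating trait between the small-winged and
large-winged lime clusters — is the wing area as a percentage of the
blade area.  Areas are conventionally reported in multiples of pi mm^2.
"""

from __future__ import annotations

import math

import pandas as pd

#: required columns of a per-leaf measurement table
MEASUREMENT_COLUMNS = (
    "accession",
    "blade_length_mm",
    "blade_width_mm",
    "wing_length_mm",
    "wing_width_mm",
)


def ellipse_area(length: float, width: float, pi_units: bool = False) -> float:
    """Ellipse area from its two axis lengths (mm -> mm^2).

    With ``pi_units=True`` the result is expressed in pi mm^2 (i.e. the
    plain product of the semi-axes), the convention used for reporting
    leaf areas.
    """
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    semi = (width / 2.0) * (length / 2.0)
    return semi if pi_units else semi * math.pi


def wing_index(wing_area: float, blade_area: float) -> float:
    """Wing area as a percentage of blade area: ``100 * wing / blade``.

    Dimensionless, so the two areas may be in mm^2 or in pi-units as
    long as they agree.
    """
    if blade_area <= 0:
        raise ValueError("blade_area must be positive")
    if wing_area < 0:
        raise ValueError("wing_area must be non-negative")
    return 100.0 * wing_area / blade_area


def group_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-accession mean +- sd of leaf areas and wing index.

    Per-leaf blade/wing areas and per-leaf wing indices are computed
    first, then averaged within accession — the wing-index column is a
    mean of per-leaf ratios, not the ratio of mean areas (the two agree
    only for identical leaves).  Areas are reported in pi mm^2.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    if measurements.empty:
        raise ValueError("no measurements given")
    df = measurements.copy()
    df["blade_area_pi"] = [
        ellipse_area(l, w, pi_units=True)
        for l, w in zip(df["blade_length_mm"], df["blade_width_mm"])
    ]
    df["wing_area_pi"] = [
        ellipse_area(l, w, pi_units=True)
        for l, w in zip(df["wing_length_mm"], df["wing_width_mm"])
    ]
    df["wing_index"] = [
        wing_index(w, b) for w, b in zip(df["wing_area_pi"], df["blade_area_pi"])
    ]
    g = df.groupby("accession", sort=False)
    out = pd.DataFrame(
        {
            "n_leaves": g.size(),
            "blade_area_pi_mean": g["blade_area_pi"].mean(),
            "blade_area_pi_sd": g["blade_area_pi"].std(ddof=1).fillna(0.0),
            "wing_area_pi_mean": g["wing_area_pi"].mean(),
            "wing_area_pi_sd": g["wing_area_pi"].std(ddof=1).fillna(0.0),
            "wing_index_mean": g["wing_index"].mean(),
            "wing_index_sd": g["wing_index"].std(ddof=1).fillna(0.0),
        }
    )
    out.index.name = "accession"
    return out


def read_measurements(source: str) -> pd.DataFrame:
    """Parse a per-leaf TSV with the :data:`MEASUREMENT_COLUMNS` (an
    optional ``leaf_id`` column is carried through untouched)."""
    from io import StringIO

    df = pd.read_csv(StringIO(source), sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    return df
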