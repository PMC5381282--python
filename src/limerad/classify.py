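"""Genotypable-site filtering and Category A-L site classification.

Every genotypable site (complete call in all accessions, and informative:
at least one heterozygous call or at least two distinct homozygous calls)
receives exactly one of thirteen labels.  Twelve of them (A-L) describe
genotype combinations over a two-cluster accession partition — e.g.
Category C is "one heterozygous code uniform across the first cluster,
one homozygous call uniform across the second" — and a residual bucket U
collects all-homozygous combinations the twelve classes do not cover, so
that the labels always partition the genotypable sites.

Labelling is an ordered decision procedure.  Multi-het sites (>=2
distinct ambiguity codes) are resolved first because Category L is the
only class describing them; uniformity is defined on calls, not alleles
(``A,A,A,M`` is non-uniform even though M resolves to A/C).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import (
    GenotypeError,
    GenotypeMatrix,
    ClusterPartition,
    HET_TO_ALLELES,
    HOM_CODES,
    MISSING,
)

CATEGORY_LABELS: tuple[str, ...] = tuple("ABCDEFGHIJKLU")


def het_status(code: str) -> tuple[str, tuple[str, ...]]:
    """Classify one call as heterozygous or homozygous.

    Returns ``("heterozygous", (x, y))`` with the two resolved
    nucleotides for an ambiguity code, or ``("homozygous", (code,))``
    for a plain nucleotide.  Missing calls are the caller's problem and
    raise.
    """
    if code in HET_TO_ALLELES:
        return "heterozygous", HET_TO_ALLELES[code]
    if code in HOM_CODES:
        return "homozygous", (code,)
    raise GenotypeError(f"cannot assess het status of {code!r}")


def is_het(code: str) -> bool:
    return code in HET_TO_ALLELES


def filter_genotypable(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, list[int]]:
    """Keep the sites usable for genotype comparison.

    A site survives iff (i) no accession is missing a call there and
    (ii) it is informative: some heterozygous call is present, or at
    least two distinct homozygous calls are.  Monomorphic homozygous
    sites carry no genotype information and are dropped; uniformly
    heterozygous sites are kept (they are Category A).
    """
    calls = matrix.calls
    complete = ~(calls == MISSING).any(axis=1)
    any_het = np.isin(calls, list(HET_TO_ALLELES)).any(axis=1)
    # >=2 distinct hom calls <=> not all columns equal when no het present
    uniform = (calls == calls[:, [0]]).all(axis=1)
    informative = any_het | ~uniform
    kept = np.flatnonzero(complete & informative)
    return matrix.take_sites(kept), [int(i) for i in kept]


def classify_site(calls, partition: ClusterPartition, accession_ids) -> str:
    """Assign one genotypable site its category label.

    ``calls`` holds one call per accession in the order of
    ``accession_ids``; the partition's first cluster plays the
    "Bhutanese" role in the class definitions.
    """
    b_idx, i_idx = partition.split_indices(list(accession_ids))
    return _classify_core([str(c).upper() for c in calls], b_idx, i_idx)


def _classify_core(calls: list[str], b_idx: list[int], i_idx: list[int]) -> str:
    if any(c == MISSING for c in calls):
        raise GenotypeError("classify_site requires a complete site (no missing calls)")
    het_codes = {c for c in calls if c in HET_TO_ALLELES}
    if not het_codes and len(set(calls)) < 2:
        raise GenotypeError("monomorphic homozygous site is not genotypable")

    if len(het_codes) >= 2:
        return "L"
    B = [calls[k] for k in b_idx]
    I = [calls[k] for k in i_idx]
    if len(set(calls)) == 1 and het_codes:
        return "A"
    b_set, i_set = set(B), set(I)
    b_uni, i_uni = len(b_set) == 1, len(i_set) == 1

    if b_uni and i_uni:
        b_het, i_het = is_het(B[0]), is_het(I[0])
        if not b_het and not i_het:
            return "B"
        if b_het and not i_het:
            return "C"
        return "D"  # hom/het; het/het uniform with one code is all-identical -> A

    if het_codes:
        H = next(iter(het_codes))
        allowed = {H, *HET_TO_ALLELES[H]}
        if b_uni and B[0] == H and i_set <= allowed:
            return "E"
        if i_uni and I[0] == H and b_set <= allowed:
            return "F"
        if b_uni and B[0] in HOM_CODES and H in i_set and i_set <= allowed:
            return "G"
        if i_uni and I[0] in HOM_CODES and H in b_set and b_set <= allowed:
            return "H"
        return "I"

    # all-homozygous, non-trivial combinations
    if b_uni and B[0] in i_set:
        return "J"
    if i_uni and not b_uni:
        return "K"
    return "U"


@dataclass
class CategoryReport:
    """Per-site category labels plus the per-category tally.

    ``per_site`` is aligned with the *filtered* matrix; ``kept_sites``
    maps its rows back to the input matrix.  Counts over all thirteen
    labels always sum to ``n_sites_genotypable``.
    """

    per_site: np.ndarray
    counts: dict[str, int]
    n_sites_total: int
    n_sites_genotypable: int
    kept_sites: list[int]

    def to_dict(self) -> dict:
        return {
            "n_sites_total": self.n_sites_total,
            "n_sites_genotypable": self.n_sites_genotypable,
            "counts": {k: self.counts[k] for k in CATEGORY_LABELS},
        }


def classify_matrix(
    matrix: GenotypeMatrix,
    partition: ClusterPartition,
    prefiltered: bool = False,
) -> tuple[CategoryReport, GenotypeMatrix]:
    """Label every genotypable site and tally categories.

    Returns the report and the filtered matrix its ``per_site`` labels
    refer to.  Set ``prefiltered=True`` if the matrix has already been
    through :func:`filter_genotypable`.
    """
    partition.validate_against(matrix.accession_ids)
    if prefiltered:
        filtered, kept = matrix, list(range(matrix.n_sites))
    else:
        filtered, kept = filter_genotypable(matrix)
    b_idx, i_idx = partition.split_indices(filtered.accession_ids)
    labels = np.array(
        [
            _classify_core(list(filtered.calls[i]), b_idx, i_idx)
            for i in range(filtered.n_sites)
        ],
        dtype="U1",
    )
    counts = Counter(labels.tolist())
    report = CategoryReport(
        per_site=labels,
        counts={lab: int(counts.get(lab, 0)) for lab in CATEGORY_LABELS},
        n_sites_total=matrix.n_sites,
        n_sites_genotypable=filtered.n_sites,
        kept_sites=kept,
    )
    return report, filtered
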