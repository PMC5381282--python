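"""Heterozygosity, genotype-match, and subcluster-pattern statistics.

These are the summary statistics a clonal-lineage RAD-seq comparison
reads off a classified genotype matrix: per-accession heterozygous-call
counts and their frequency over all analyzed bases, pairwise
identical-genotype counts within a site subset, within-group identity
tallies, the three-way consensus pattern tables that contrast the
non-subclustered cluster with the two subclusters, and the back-of-the-
envelope estimator converting a category's event count into the number
of de novo mutations attributable to the restriction-enzyme recognition
site itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CategoryReport, is_het
from .io import ClusterPartition, GenotypeMatrix, HET_TO_ALLELES, PartitionError


def total_bases(n_loci: int, read_length: int) -> int:
    """Total analyzed bases: loci count x read length (e.g. 78,527 x 41 bp
    single-end RAD tags = 3,219,607 bp)."""
    if n_loci <= 0 or read_length <= 0:
        raise ValueError("n_loci and read_length must be positive")
    return int(n_loci) * int(read_length)


def het_stats(matrix: GenotypeMatrix, total_bases: int) -> pd.DataFrame:
    """Per-accession heterozygous genotype counts and frequencies.

    The count is the number of genotypable sites carrying a heterozygous
    call — a floor on the accession's true heterozygosity, since only
    sites that survived genotyping are counted.  The frequency is
    ``100 * count / total_bases`` (percent of all analyzed bases), full
    precision in ``het_pct`` with a 2-decimal presentation column.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    het = np.isin(matrix.calls, list(HET_TO_ALLELES))
    counts = het.sum(axis=0)
    pct = 100.0 * counts / total_bases
    return pd.DataFrame(
        {
            "het_sites": counts.astype(int),
            "total_bases": int(total_bases),
            "het_pct": pct,
            "het_pct_2dp": np.round(pct, 2),
        },
        index=pd.Index(matrix.accession_ids, name="accession"),
    )


def pairwise_matches(
    matrix: GenotypeMatrix,
    site_subset=None,
    accessions=None,
) -> pd.DataFrame:
    """Count identical-call sites for every accession pair within a site
    subset.  Symmetric; the diagonal equals the subset size."""
    accs = list(accessions) if accessions is not None else list(matrix.accession_ids)
    unknown = [a for a in accs if a not in matrix.accession_ids]
    if unknown:
        raise KeyError(f"unknown accession(s): {unknown}")
    cols = [matrix.accession_ids.index(a) for a in accs]
    idx = (
        np.arange(matrix.n_sites)
        if site_subset is None
        else np.asarray(list(site_subset), dtype=int)
    )
    sub = matrix.calls[np.ix_(idx, cols)]
    n = len(accs)
    out = np.zeros((n, n), dtype=int)
    for a in range(n):
        out[a, a] = len(idx)
        for b in range(a + 1, n):
            m = int((sub[:, a] == sub[:, b]).sum())
            out[a, b] = out[b, a] = m
    return pd.DataFrame(out, index=accs, columns=accs)


def cluster_identity_counts(
    matrix: GenotypeMatrix,
    partition: ClusterPartition,
    group: str,
) -> tuple[int, int]:
    """(identical, non_identical) site counts for one cluster/subcluster:
    sites where all group members carry the same call versus not.  The
    two always sum to the matrix's site count."""
    members = partition.members(group)
    cols = [matrix.accession_ids.index(a) for a in members]
    sub = matrix.calls[:, cols]
    identical = int((sub == sub[:, [0]]).all(axis=1).sum())
    return identical, matrix.n_sites - identical


@dataclass
class SubpatternTable:
    """Consensus-triple tally for one category over the subcluster split.

    ``rows`` columns: consensus of the non-subclustered cluster, of
    subcluster 1, of subcluster 2, and the site count; only sites where
    *both* subclusters are internally uniform contribute a row, the rest
    go to ``remainder_count``.  ``sub1_het_sub2_hom`` and
    ``sub1_hom_sub2_het`` are the two directional totals (sums of the
    corresponding rows).
    """

    category: str
    rows: pd.DataFrame
    remainder_count: int
    sub1_het_sub2_hom: int
    sub1_hom_sub2_het: int

    @property
    def category_count(self) -> int:
        return int(self.rows["count"].sum()) + self.remainder_count


SUBPATTERN_CATEGORIES = ("E", "G", "J")


def subpattern_table(
    matrix: GenotypeMatrix,
    partition: ClusterPartition,
    report: CategoryReport,
    category: str,
) -> SubpatternTable:
    """Tabulate (other-cluster, subcluster-1, subcluster-2) consensus
    triples for the sites of one category.

    ``matrix`` must be the filtered matrix the report's ``per_site``
    labels refer to.  Supported categories are the ones whose definition
    involves within-cluster variation that the subcluster split can
    explain: E and G (het/hom mixtures inside the subclustered cluster)
    and J (all-homozygous mixtures).
    """
    if category not in SUBPATTERN_CATEGORIES:
        raise ValueError(
            f"category {category!r} has no subcluster pattern semantics "
            f"(supported: {SUBPATTERN_CATEGORIES})"
        )
    if partition.subcluster_order is None:
        raise PartitionError("partition declares no subclusters")
    if len(report.per_site) != matrix.n_sites:
        raise ValueError("report does not match matrix (pass the filtered matrix)")
    other_cluster = next(
        c for c in partition.cluster_order if c != partition.subclustered_cluster
    )
    other_cols = [matrix.accession_ids.index(a) for a in partition.members(other_cluster)]
    s1_cols, s2_cols = partition.subcluster_indices(matrix.accession_ids)

    tally: dict[tuple[str, str, str], int] = {}
    remainder = 0
    for i in np.flatnonzero(report.per_site == category):
        calls = matrix.calls[i]
        s1 = {str(calls[k]) for k in s1_cols}
        s2 = {str(calls[k]) for k in s2_cols}
        other = {str(calls[k]) for k in other_cols}
        if len(s1) != 1 or len(s2) != 1:
            remainder += 1
            continue
        # the non-subclustered cluster is uniform for E/G/J sites by definition
        triple = (next(iter(other)), next(iter(s1)), next(iter(s2)))
        tally[triple] = tally.get(triple, 0) + 1

    rows = pd.DataFrame(
        [(*k, v) for k, v in sorted(tally.items())],
        columns=["other_cluster", "subcluster1", "subcluster2", "count"],
    )
    if rows.empty:
        rows = pd.DataFrame(
            columns=["other_cluster", "subcluster1", "subcluster2", "count"]
        ).astype({"count": int})
    d1 = int(
        rows.loc[
            rows["subcluster1"].map(is_het) & ~rows["subcluster2"].map(is_het), "count"
        ].sum()
    ) if not rows.empty else 0
    d2 = int(
        rows.loc[
            ~rows["subcluster1"].map(is_het) & rows["subcluster2"].map(is_het), "count"
        ].sum()
    ) if not rows.empty else 0
    return SubpatternTable(
        category=category,
        rows=rows,
        remainder_count=remainder,
        sub1_het_sub2_hom=d1,
        sub1_hom_sub2_het=d2,
    )


def ecori_denovo_estimate(
    n_events: int, site_length: int = 6, flank_length: int = 36
) -> int:
    """Number of de novo mutations expected to hit the restriction site
    itself, scaled from the events observed in its flanking sequence.

    RAD tags here are 41-bp reads: a 6-bp kept restriction motif
    (AATTC read + 1) plus 36 bp of flank.  If mutations fall uniformly,
    events in the 6-bp recognition site occur at ``site_length /
    flank_length`` times the observed flank events; the result is
    rounded half-up (3087 flank events -> 3087/6 = 514.5 -> 515).
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    if site_length <= 0 or flank_length <= 0:
        raise ValueError("site_length and flank_length must be positive")
    if n_events == 0:
        return 0
    return int(math.floor(n_events * site_length / flank_length + 0.5))
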