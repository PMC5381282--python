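"""Synthetic clonal-lineage genotype matrices with full ground truth.

The generative model mirrors how an asexually propagated, highly
heterozygous founder (a hybrid-origin citrus clone) diversifies into the
observed accession panel:

* the founder is heterozygous at each site with probability ``p_het``
  (uniform over the six ambiguity codes), otherwise homozygous (uniform
  over the four nucleotides);
* genotypes propagate down a fixed lineage tree; on every branch,
  independently per site, a heterozygote undergoes loss of
  heterozygosity (LOH, somatic homologous recombination) with
  probability ``r_loh`` and becomes one of its two homozygous
  resolutions (each 1/2), and a homozygote acquires a de novo mutation
  with probability ``r_mut``, becoming the heterozygote joining it with
  a uniformly chosen other nucleotide;
* at the tips, observation noise is applied: restriction-site allele
  dropout (a heterozygote read as a homozygote of one random allele,
  probability ``r_dropout`` — the "false-positive homozygous genotype"
  artifact of losing the enzyme site on one haplotype), then call error
  (replacement by a uniformly random other permitted call, probability
  ``e_error``).

An optional tract mode replaces per-site LOH with geometric-length
recombination tracts, reflecting that double-strand-break repair can
homogenize larger regions; the per-site mode is the analytically
tractable default.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CategoryReport, classify_matrix
from .io import (
    ALLELES_TO_HET,
    DEFAULT_ACCESSIONS,
    CALL_CODES,
    ClusterPartition,
    GenotypeMatrix,
    HET_CODES,
    HET_TO_ALLELES,
    HOM_CODES,
    default_partition,
)

FOUNDER = "founder"


@dataclass(frozen=True)
class LineageBranch:
    """One branch of the clonal lineage tree with its event rates."""

    parent: str
    child: str
    r_loh: float = 0.0
    r_mut: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("r_loh", self.r_loh), ("r_mut", self.r_mut)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class SimParams:
    n_sites: int
    p_het: float
    branches: list[LineageBranch]
    r_dropout: float = 0.0
    e_error: float = 0.0
    seed: int = 0
    loh_mode: str = "site"
    tract_mean_length: float = 100.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name, p in (
            ("p_het", self.p_het),
            ("r_dropout", self.r_dropout),
            ("e_error", self.e_error),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.loh_mode not in ("site", "tract"):
            raise ValueError("loh_mode must be 'site' or 'tract'")
        if self.tract_mean_length < 1.0:
            raise ValueError("tract_mean_length must be >= 1")
        self._validate_tree()

    def _validate_tree(self) -> None:
        children = [b.child for b in self.branches]
        if len(set(children)) != len(children):
            raise ValueError("each node may have only one parent branch")
        parents = {b.parent for b in self.branches}
        roots = parents - set(children)
        if roots != {FOUNDER}:
            raise ValueError(f"tree must be rooted at {FOUNDER!r}, roots: {sorted(roots)}")
        # every non-root parent must itself be reachable from the founder
        reachable = {FOUNDER}
        pending = list(self.branches)
        progress = True
        while pending and progress:
            progress = False
            for b in list(pending):
                if b.parent in reachable:
                    reachable.add(b.child)
                    pending.remove(b)
                    progress = True
        if pending:
            raise ValueError("tree contains branches unreachable from the founder")

    @property
    def tips(self) -> list[str]:
        parents = {b.parent for b in self.branches}
        return [b.child for b in self.branches if b.child not in parents]


@dataclass
class SimResult:
    """Simulated matrix plus the ground truth that produced it.

    ``truth`` keys: ``founder`` (per-site founder call), ``pre_noise``
    (tip genotypes before dropout/error, as a GenotypeMatrix),
    ``true_category`` (the category each site would occupy absent
    observation noise; ``"."`` for sites not genotypable even without
    noise), ``events`` (per branch child, site indices of LOH and
    mutation events).
    """

    matrix: GenotypeMatrix
    truth: dict
    params: SimParams


def default_lineage_tree(
    loh: float | dict = 0.0, mut: float | dict = 0.0
) -> list[LineageBranch]:
    """The eight-tip lime lineage: founder -> Bhutanese ancestor -> four
    tips, and founder -> Indonesian ancestor -> two subcluster ancestors
    -> two tips each.

    ``loh``/``mut`` are either a single rate for all branches or a dict
    keyed by child node name (missing keys default to 0).
    """

    def rate(given, child):
        if isinstance(given, dict):
            return float(given.get(child, 0.0))
        return float(given)

    edges = [
        (FOUNDER, "bhutanese_ancestor"),
        (FOUNDER, "indonesian_ancestor"),
        ("bhutanese_ancestor", "Bhutan-09015"),
        ("bhutanese_ancestor", "Bhutan-09024"),
        ("bhutanese_ancestor", "Bhutan-09027"),
        ("bhutanese_ancestor", "Bhutan-09030"),
        ("indonesian_ancestor", "subcluster1_ancestor"),
        ("indonesian_ancestor", "subcluster2_ancestor"),
        ("subcluster1_ancestor", "Bhutan-09005"),
        ("subcluster1_ancestor", "Indonesia-88065"),
        ("subcluster2_ancestor", "Indonesia-88035"),
        ("subcluster2_ancestor", "Indonesia-88045"),
    ]
    return [
        LineageBranch(p, c, r_loh=rate(loh, c), r_mut=rate(mut, c)) for p, c in edges
    ]


def paperlike_params(n_sites: int = 40_000, seed: int = 0) -> SimParams:
    """Preset emulating the shape of the real lime panel: ~56% of
    genotypable sites heterozygous per accession, category mass
    concentrated in A/C/D (maintained founder heterozygosity eroded by
    heavy LOH on the two cluster-ancestor branches), small E-L tails
    from subcluster-branch LOH, rare de novo mutation, and light
    dropout/error noise."""
    tip_loh = {t: 0.004 for t in DEFAULT_ACCESSIONS}
    loh = {
        "bhutanese_ancestor": 0.48,
        "indonesian_ancestor": 0.54,
        "subcluster1_ancestor": 0.03,
        "subcluster2_ancestor": 0.05,
        **tip_loh,
    }
    mut = {
        "bhutanese_ancestor": 0.003,
        "indonesian_ancestor": 0.003,
        "subcluster1_ancestor": 0.0005,
        "subcluster2_ancestor": 0.0005,
    }
    return SimParams(
        n_sites=n_sites,
        p_het=0.60,
        branches=default_lineage_tree(loh=loh, mut=mut),
        r_dropout=0.002,
        e_error=0.0003,
        seed=seed,
    )


_OTHER_NUC = {h: [n for n in HOM_CODES if n != h] for h in HOM_CODES}
_OTHER_CALL = {c: [x for x in CALL_CODES if x != c] for c in CALL_CODES}


def _resolve_het(codes: np.ndarray, side: np.ndarray) -> np.ndarray:
    """Resolve het codes to one allele: side 0 -> first of the pair."""
    return np.array(
        [HET_TO_ALLELES[c][s] for c, s in zip(codes.tolist(), side.tolist())],
        dtype="U1",
    )


def _loh_mask(
    het_mask: np.ndarray, r_loh: float, rng, mode: str, tract_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Which sites undergo LOH on this branch, and which haplotype side
    each resolved site keeps."""
    n = het_mask.size
    if mode == "site":
        mask = het_mask & (rng.random(n) < r_loh)
        side = rng.integers(0, 2, size=n)
        return mask, side
    # tract mode: starts at rate r_loh / mean length, geometric extent,
    # one haplotype side per tract
    mask = np.zeros(n, dtype=bool)
    side = np.zeros(n, dtype=np.int64)
    starts = np.flatnonzero(rng.random(n) < r_loh / tract_mean)
    for s in starts:
        length = int(rng.geometric(1.0 / tract_mean))
        h = int(rng.integers(0, 2))
        end = min(n, s + length)
        mask[s:end] = True
        side[s:end] = h
    return mask & het_mask, side


def _apply_branch(
    genotypes: np.ndarray, branch: LineageBranch, rng, mode: str, tract_mean: float
) -> tuple[np.ndarray, dict]:
    g = genotypes.copy()
    het_mask = np.isin(g, list(HET_CODES))
    loh_idx = np.array([], dtype=int)
    mut_idx = np.array([], dtype=int)
    if branch.r_loh > 0:
        mask, side = _loh_mask(het_mask, branch.r_loh, rng, mode, tract_mean)
        loh_idx = np.flatnonzero(mask)
        if loh_idx.size:
            g[loh_idx] = _resolve_het(g[loh_idx], side[loh_idx])
    if branch.r_mut > 0:
        hom_mask = np.isin(g, list(HOM_CODES))
        mut_mask = hom_mask & (rng.random(g.size) < branch.r_mut)
        mut_idx = np.flatnonzero(mut_mask)
        if mut_idx.size:
            picks = rng.integers(0, 3, size=mut_idx.size)
            g[mut_idx] = [
                ALLELES_TO_HET[frozenset((c, _OTHER_NUC[c][k]))]
                for c, k in zip(g[mut_idx].tolist(), picks.tolist())
            ]
    return g, {"loh": loh_idx, "mut": mut_idx}


def simulate(params: SimParams, partition: ClusterPartition | None = None) -> SimResult:
    """Run the clonal diversification model.

    The optional ``partition`` is used only to compute the noise-free
    truth categories; when omitted and the tree's tips are the default
    eight-accession panel, the shipped partition is used.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_sites

    founder = np.empty(n, dtype="U1")
    is_het_site = rng.random(n) < params.p_het
    founder[is_het_site] = np.array(HET_CODES)[
        rng.integers(0, len(HET_CODES), size=int(is_het_site.sum()))
    ]
    founder[~is_het_site] = np.array(HOM_CODES)[
        rng.integers(0, len(HOM_CODES), size=int((~is_het_site).sum()))
    ]

    genomes = {FOUNDER: founder}
    events: dict[str, dict] = {}
    for branch in params.branches:
        genomes[branch.child], events[branch.child] = _apply_branch(
            genomes[branch.parent], branch, rng, params.loh_mode,
            params.tract_mean_length,
        )

    tips = params.tips
    site_ids = [f"chr1:{i + 1}" for i in range(n)]
    pre_noise = GenotypeMatrix(
        accession_ids=tips,
        calls=np.column_stack([genomes[t] for t in tips]),
        site_ids=site_ids,
    )

    observed = pre_noise.calls.copy()
    for j in range(len(tips)):
        col = observed[:, j]
        if params.r_dropout > 0:
            het_mask = np.isin(col, list(HET_CODES))
            drop = het_mask & (rng.random(n) < params.r_dropout)
            idx = np.flatnonzero(drop)
            if idx.size:
                col[idx] = _resolve_het(col[idx], rng.integers(0, 2, size=idx.size))
        if params.e_error > 0:
            err = rng.random(n) < params.e_error
            idx = np.flatnonzero(err)
            if idx.size:
                picks = rng.integers(0, len(CALL_CODES) - 1, size=idx.size)
                col[idx] = [
                    _OTHER_CALL[c][k] for c, k in zip(col[idx].tolist(), picks.tolist())
                ]
        observed[:, j] = col
    matrix = GenotypeMatrix(accession_ids=tips, calls=observed, site_ids=site_ids)

    if partition is None and set(tips) == set(DEFAULT_ACCESSIONS):
        partition = default_partition()
    true_category = np.full(n, ".", dtype="U1")
    if partition is not None:
        report, _ = classify_matrix(pre_noise, partition)
        true_category[report.kept_sites] = report.per_site

    return SimResult(
        matrix=matrix,
        truth={
            "founder": founder,
            "pre_noise": pre_noise,
            "true_category": true_category,
            "events": events,
        },
        params=params,
    )


def estimate_rates(result: SimResult, report: CategoryReport) -> dict:
    """Recover single-branch LOH rates from the category tally.

    In a scenario where LOH happened only on one cluster-ancestor
    branch, every founder-het site ends up Category A (no event) or in
    the het->hom class pointing at that cluster: C for the second
    (Indonesian-role) cluster's ancestor, D for the first.  The natural
    estimators are therefore ``#C / (#A + #C)`` and ``#D / (#A + #D)``.
    A zero denominator yields NaN with its flag set.
    """
    c = report.counts
    out: dict[str, float | bool] = {}
    for key, num in (("r_loh_cluster2", "C"), ("r_loh_cluster1", "D")):
        denom = c["A"] + c[num]
        out[key] = (c[num] / denom) if denom else float("nan")
        out[f"{key}_undefined"] = denom == 0
    return out
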