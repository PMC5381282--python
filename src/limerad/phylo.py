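"""Genotype distances, neighbor-joining trees, and site-bootstrap support.

The goal of the tree stage is cluster recovery: show that the accession
matrix separates into the expected two clusters (and the two subclusters
inside one of them) as bipartitions of an unrooted tree.  Distances are
computed directly on the IUPAC call matrix; trees are built with the
classic neighbor-joining agglomeration, which reconstructs topology and
path lengths exactly whenever the input distances are additive.

Determinism contracts: ties in the NJ Q-matrix are broken by the lowest
(row, column) index pair, and negative branch-length estimates are
clamped to zero with the lost length shifted onto the sister edge, so a
fixed input always yields byte-identical Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .io import CALL_CODES, GenotypeMatrix, MISSING, alleles_of

_CODE_INDEX = {c: k for k, c in enumerate(CALL_CODES)}


def _allele_sharing_table() -> np.ndarray:
    """10x10 per-site score table: 0 identical call, 0.5 one shared
    allele, 1 disjoint allele sets."""
    n = len(CALL_CODES)
    tab = np.ones((n, n))
    for a, ca in enumerate(CALL_CODES):
        for b, cb in enumerate(CALL_CODES):
            if ca == cb:
                tab[a, b] = 0.0
            elif set(alleles_of(ca)) & set(alleles_of(cb)):
                tab[a, b] = 0.5
    return tab


_SHARING = _allele_sharing_table()

METRICS = ("mismatch", "allele_sharing")


def genotype_distance(matrix: GenotypeMatrix, metric: str = "mismatch") -> DistanceMatrix:
    """Pairwise accession distances in [0, 1].

    ``mismatch`` is the fraction of sites with non-identical calls;
    ``allele_sharing`` averages a per-site allele score (identical call
    0, one shared allele 0.5, disjoint allele sets 1, so a heterozygote
    scores 0.5 against either of its homozygous resolutions).  Sites
    where either accession is missing are excluded pairwise.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r} (choose from {METRICS})")
    if matrix.n_sites < 1 or matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions and 1 site")
    n = matrix.n_accessions
    calls = matrix.calls
    codes = np.full(calls.shape, -1, dtype=int)
    for c, k in _CODE_INDEX.items():
        codes[calls == c] = k
    present = calls != MISSING
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            valid = present[:, a] & present[:, b]
            if not valid.any():
                raise ValueError(
                    f"no jointly called sites between "
                    f"{matrix.accession_ids[a]!r} and {matrix.accession_ids[b]!r}"
                )
            if metric == "mismatch":
                d = float((calls[valid, a] != calls[valid, b]).mean())
            else:
                d = float(_SHARING[codes[valid, a], codes[valid, b]].mean())
            out[a, b] = out[b, a] = d
    return DistanceMatrix(out, ids=matrix.accession_ids)


@dataclass
class TreeNode:
    """Minimal rooted representation of the (unrooted) NJ result."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["TreeNode"]:
        if self.is_tip:
            return [self]
        return [t for c in self.children for t in c.tips()]

    def tip_names(self) -> frozenset:
        return frozenset(t.name for t in self.tips())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def bipartitions(self) -> set:
        """Non-trivial splits of the tip set, each represented by the
        side not containing a fixed reference tip (rooting-invariant)."""
        all_tips = self.tip_names()
        ref = min(all_tips)
        splits = set()
        for node in self.walk():
            if node is self or node.is_tip:
                continue
            side = node.tip_names()
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= len(all_tips) - 2:
                splits.add(side)
        return splits

    def tip_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all tips."""
        names = sorted(self.tip_names())
        idx = {n: i for i, n in enumerate(names)}
        dist = np.zeros((len(names), len(names)))

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_tip:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            done: list[dict[str, float]] = []
            for child in node.children:
                d = {t: v + child.length for t, v in below(child).items()}
                for prev in done:
                    for t1, v1 in prev.items():
                        for t2, v2 in d.items():
                            dist[idx[t1], idx[t2]] = dist[idx[t2], idx[t1]] = v1 + v2
                done.append(d)
                acc.update(d)
            return acc

        below(self)
        return DistanceMatrix(dist, ids=names)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou-Nei agglomeration.  With two taxa the result is the
    single forced edge (length split evenly around the arbitrary root);
    three or more taxa follow the usual Q-matrix criterion.  Negative
    branch-length estimates are clamped to zero and their magnitude moved
    to the sister edge so total path lengths are preserved.
    """
    ids = list(d.ids)
    D = np.array(d.data, dtype=float)
    nodes = [TreeNode(name=i) for i in ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(ids) == 2:
        nodes[0].length = nodes[1].length = D[0, 1] / 2.0
        return TreeNode(children=nodes)

    active = list(range(len(ids)))
    while len(active) > 2:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: first (row, col) attaining the minimum
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, n)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every remaining one
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        k = D.shape[0] - 1
        for pos, other in enumerate(active):
            D[k, other] = D[other, k] = new_row[pos]
        D[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    # final edge: attach halves to either side of the arbitrary root
    nodes[i].length = nodes[j].length = D[i, j] / 2.0
    return TreeNode(children=[nodes[i], nodes[j]])


def bootstrap_support(
    matrix: GenotypeMatrix,
    metric: str = "mismatch",
    reps: int = 100,
    seed: int | None = None,
) -> tuple[TreeNode, dict]:
    """NJ tree with site-bootstrap support on internal edges.

    Sites are resampled with replacement ``reps`` times; support for
    each bipartition of the full-data tree is the percentage of
    replicate trees containing it.  Returns the annotated tree and a
    ``{bipartition: percent}`` map.
    """
    if reps < 0:
        raise ValueError("reps must be non-negative")
    tree = nj_tree(genotype_distance(matrix, metric))
    splits = tree.bipartitions()
    hits = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        idx = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        rep_tree = nj_tree(genotype_distance(matrix.take_sites(idx), metric))
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    support = {
        s: (100.0 * h / reps if reps else float("nan")) for s, h in hits.items()
    }
    all_tips = tree.tip_names()
    ref = min(all_tips)
    for node in tree.walk():
        if node is tree or node.is_tip:
            continue
        side = node.tip_names()
        if ref in side:
            side = all_tips - side
        if side in support:
            node.support = support[side]
    return tree, support


def build_tree(
    matrix: GenotypeMatrix,
    metric: str = "mismatch",
    bootstrap: int = 0,
    seed: int | None = None,
) -> str:
    """Convenience wrapper: distance -> NJ (-> bootstrap) -> Newick text."""
    if matrix.n_accessions < 3:
        import warnings

        warnings.warn("fewer than 3 taxa: returning the degenerate tree")
    if bootstrap:
        tree, _ = bootstrap_support(matrix, metric, bootstrap, seed)
        return tree.to_newick(with_support=True)
    return nj_tree(genotype_distance(matrix, metric)).to_newick()
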