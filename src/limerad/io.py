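"""Readers and writers for IUPAC genotype matrices and cluster partitions.

Diploid single-nucleotide genotypes are encoded as one character per site
per accession: ``A/C/G/T`` for homozygotes, the six IUPAC two-allele
ambiguity codes for heterozygotes (``M``=A/C, ``R``=A/G, ``W``=A/T,
``S``=C/G, ``Y``=C/T, ``K``=G/T), and ``N`` for a missing call.  The
on-disk formats are aligned FASTA (one record per accession), a simple
TSV dialect (header = accession ids, one row per site, optional leading
``site_id`` column), and a VCF 4.2 export.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import SeqIO

HET_TO_ALLELES: dict[str, tuple[str, str]] = {
    "M": ("A", "C"),
    "R": ("A", "G"),
    "W": ("A", "T"),
    "S": ("C", "G"),
    "Y": ("C", "T"),
    "K": ("G", "T"),
}
ALLELES_TO_HET: dict[frozenset, str] = {
    frozenset(v): k for k, v in HET_TO_ALLELES.items()
}
HOM_CODES: tuple[str, ...] = ("A", "C", "G", "T")
HET_CODES: tuple[str, ...] = tuple(HET_TO_ALLELES)
MISSING = "N"
#: the ten informative call codes (no missing marker)
CALL_CODES: tuple[str, ...] = HOM_CODES + HET_CODES
ALPHABET: frozenset = frozenset(CALL_CODES) | {MISSING}


class GenotypeError(ValueError):
    """A call outside the 11-symbol alphabet, or a malformed matrix."""


class AlignmentLengthError(GenotypeError):
    """Accession sequences of unequal length."""


class PartitionError(ValueError):
    """An invalid or inconsistent cluster partition."""


def alleles_of(code: str) -> tuple[str, ...]:
    """Resolved nucleotide(s) of a call: two for het codes, one for homs."""
    if code in HET_TO_ALLELES:
        return HET_TO_ALLELES[code]
    if code in HOM_CODES:
        return (code,)
    raise GenotypeError(f"cannot resolve alleles of {code!r}")


@dataclass
class GenotypeMatrix:
    """A sites x accessions grid of single-character IUPAC calls.

    Parameters
    ----------
    accession_ids
        Ordered, unique accession labels (columns).
    calls
        ``(n_sites, n_accessions)`` array of single characters.
    site_ids
        Optional per-site locus labels, conventionally ``"chrom:pos"``
        with a 1-based position (required for VCF export).
    """

    accession_ids: list[str]
    calls: np.ndarray
    site_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.calls = np.asarray(self.calls, dtype="U1")
        if self.calls.ndim != 2:
            raise GenotypeError("calls must be a 2-D (sites x accessions) array")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise GenotypeError("duplicate accession id")
        if not self.accession_ids:
            raise GenotypeError("at least one accession required")
        if self.calls.shape[1] != len(self.accession_ids):
            raise GenotypeError(
                f"{self.calls.shape[1]} call columns for "
                f"{len(self.accession_ids)} accessions"
            )
        if self.site_ids is not None:
            self.site_ids = [str(s) for s in self.site_ids]
            if len(self.site_ids) != self.calls.shape[0]:
                raise GenotypeError("site_ids length does not match site count")
        bad = ~np.isin(self.calls, list(ALPHABET))
        if bad.any():
            s, a = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid call {self.calls[s, a]!r} at site {s} "
                f"(accession {self.accession_ids[a]!r})"
            )

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[1]

    def column(self, accession_id: str) -> np.ndarray:
        """All calls of one accession, in site order."""
        return self.calls[:, self.accession_ids.index(accession_id)]

    def sequence(self, accession_id: str) -> str:
        return "".join(self.column(accession_id))

    def take_sites(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            accession_ids=self.accession_ids,
            calls=self.calls[idx],
            site_ids=[self.site_ids[i] for i in idx] if self.site_ids else None,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.calls.shape == other.calls.shape
            and bool((self.calls == other.calls).all())
            and self.site_ids == other.site_ids
        )


@dataclass
class ClusterPartition:
    """Assignment of accessions to exactly two clusters, with an optional
    two-way subcluster split inside one of them.

    ``cluster_order`` fixes which cluster plays the "first" role in the
    site-category definitions (the Bhutanese role in the shipped lime
    partition); the other cluster is the one whose internal structure the
    subclusters describe in the default configuration.
    """

    cluster_order: tuple[str, str]
    cluster_of: dict[str, str]
    subclustered_cluster: str | None = None
    subcluster_order: tuple[str, str] | None = None
    subcluster_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clusters = set(self.cluster_of.values())
        if len(self.cluster_order) != 2 or set(self.cluster_order) != clusters:
            raise PartitionError(
                f"exactly 2 clusters required, got {sorted(clusters)}"
            )
        for label in self.cluster_order:
            if not self.members(label):
                raise PartitionError(f"cluster {label!r} is empty")
        if self.subclustered_cluster is not None:
            if self.subclustered_cluster not in self.cluster_order:
                raise PartitionError(
                    f"unknown subclustered cluster {self.subclustered_cluster!r}"
                )
            if self.subcluster_order is None or len(self.subcluster_order) != 2:
                raise PartitionError("exactly 2 subclusters required")
            parent = set(self.members(self.subclustered_cluster))
            assigned = set(self.subcluster_of)
            if assigned != parent:
                raise PartitionError(
                    "subclusters must partition their cluster exactly"
                )
            for label in self.subcluster_order:
                if label not in set(self.subcluster_of.values()):
                    raise PartitionError(f"subcluster {label!r} is empty")
        elif self.subcluster_of:
            raise PartitionError("subcluster assignments without a declared cluster")

    @property
    def accessions(self) -> list[str]:
        return list(self.cluster_of)

    def members(self, group: str) -> list[str]:
        """Accessions of a cluster or subcluster label, in config order."""
        if group in self.cluster_order:
            return [a for a, c in self.cluster_of.items() if c == group]
        if self.subcluster_order and group in self.subcluster_order:
            return [a for a, s in self.subcluster_of.items() if s == group]
        raise PartitionError(f"unknown group {group!r}")

    def split_indices(self, accession_ids: list[str]) -> tuple[list[int], list[int]]:
        """Column indices of the first and second cluster, validated
        against a matrix's accession ordering."""
        self.validate_against(accession_ids)
        pos = {a: i for i, a in enumerate(accession_ids)}
        first, second = self.cluster_order
        return (
            [pos[a] for a in self.members(first)],
            [pos[a] for a in self.members(second)],
        )

    def subcluster_indices(self, accession_ids: list[str]) -> tuple[list[int], list[int]]:
        if self.subcluster_order is None:
            raise PartitionError("no subclusters declared")
        pos = {a: i for i, a in enumerate(accession_ids)}
        s1, s2 = self.subcluster_order
        return ([pos[a] for a in self.members(s1)], [pos[a] for a in self.members(s2)])

    def validate_against(self, accession_ids) -> None:
        mine, theirs = set(self.cluster_of), set(accession_ids)
        if mine != theirs:
            missing = sorted(theirs - mine)
            extra = sorted(mine - theirs)
            raise PartitionError(
                f"partition/matrix accession mismatch "
                f"(unassigned: {missing}, unknown: {extra})"
            )


def parse_alignment(source: str, dialect: str = "fasta") -> GenotypeMatrix:
    """Parse an aligned genotype matrix from FASTA or TSV text.

    Calls are upper-cased; ``-`` is normalized to the missing marker
    ``N``; any other character outside the 11-symbol alphabet raises
    :class:`GenotypeError` naming the site and accession.  Ragged record
    lengths raise :class:`AlignmentLengthError`.
    """
    if not source or not source.strip():
        raise GenotypeError("empty alignment source")
    if dialect == "fasta":
        ids, seqs = [], []
        for rec in SeqIO.parse(_io.StringIO(source), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        site_ids = None
    elif dialect == "tsv":
        lines = [ln for ln in source.splitlines() if ln.strip()]
        header = lines[0].rstrip("\n").split("\t")
        has_site_ids = header and header[0] == "site_id"
        ids = header[1:] if has_site_ids else header
        site_ids = [] if has_site_ids else None
        rows = []
        for ln in lines[1:]:
            fields = ln.rstrip("\n").split("\t")
            if has_site_ids:
                site_ids.append(fields[0])
                fields = fields[1:]
            if len(fields) != len(ids):
                raise AlignmentLengthError(
                    f"row with {len(fields)} calls for {len(ids)} accessions"
                )
            rows.append(fields)
        seqs = ["".join(r[j] for r in rows) for j in range(len(ids))]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not ids:
        raise GenotypeError("no records found")
    if len(set(ids)) != len(ids):
        raise GenotypeError("duplicate accession id in alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentLengthError(
            f"unequal sequence lengths: {sorted(lengths)}"
        )
    grid = np.array([list(s.upper()) for s in seqs], dtype="U1").T
    grid[grid == "-"] = MISSING
    bad = ~np.isin(grid, list(ALPHABET))
    if bad.any():
        s, a = np.argwhere(bad)[0]
        raise GenotypeError(
            f"invalid genotype character {grid[s, a]!r} at site {s} "
            f"(accession {ids[a]!r})"
        )
    return GenotypeMatrix(accession_ids=ids, calls=grid, site_ids=site_ids)


def _vcf_lines(matrix: GenotypeMatrix, ref_alleles: list[str] | None) -> list[str]:
    if matrix.site_ids is None:
        raise GenotypeError("VCF export requires site_ids with 'chrom:pos' coordinates")
    out = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.accession_ids),
    ]
    for i, sid in enumerate(matrix.site_ids):
        try:
            chrom, pos = sid.rsplit(":", 1)
            int(pos)
        except ValueError as exc:
            raise GenotypeError(
                f"site_id {sid!r} is not 'chrom:pos' (required for VCF)"
            ) from exc
        calls = matrix.calls[i]
        observed = sorted({al for c in calls if c != MISSING for al in alleles_of(c)})
        if not observed:
            observed = ["A"]  # all-missing site: placeholder REF
        ref = ref_alleles[i] if ref_alleles is not None else observed[0]
        alts = [al for al in observed if al != ref]
        allele_index = {ref: 0, **{al: j + 1 for j, al in enumerate(alts)}}
        gts = []
        for c in calls:
            if c == MISSING:
                gts.append("./.")
            else:
                pair = sorted(allele_index[al] for al in alleles_of(c)) * (
                    2 if c in HOM_CODES else 1
                )
                gts.append(f"{pair[0]}/{pair[-1] if len(pair) > 1 else pair[0]}")
        out.append(
            f"{chrom}\t{pos}\t{sid}\t{ref}\t{','.join(alts) or '.'}"
            f"\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    return out


def write_matrix(
    matrix: GenotypeMatrix,
    dialect: str = "fasta",
    ref_alleles: list[str] | None = None,
) -> str:
    """Serialize a matrix to FASTA, TSV, or VCF text.

    ``parse_alignment(write_matrix(m, d), d) == m`` for ``fasta`` (when
    ``m`` carries no site_ids) and ``tsv``.  VCF emits heterozygous codes
    as unphased diploid genotypes (het -> ``0/1`` over its REF/ALT
    resolution pair, hom-non-reference -> ``1/1``, missing -> ``./.``);
    when ``ref_alleles`` is not given the alphabetically smallest allele
    observed at each site is taken as REF.
    """
    if dialect == "fasta":
        return "".join(
            f">{a}\n{matrix.sequence(a)}\n" for a in matrix.accession_ids
        )
    if dialect == "tsv":
        header = list(matrix.accession_ids)
        rows = []
        for i in range(matrix.n_sites):
            fields = list(matrix.calls[i])
            if matrix.site_ids is not None:
                fields.insert(0, matrix.site_ids[i])
            rows.append("\t".join(fields))
        if matrix.site_ids is not None:
            header.insert(0, "site_id")
        return "\n".join(["\t".join(header), *rows]) + "\n"
    if dialect == "vcf":
        return "\n".join(_vcf_lines(matrix, ref_alleles)) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def load_partition(source: str, matrix: GenotypeMatrix | None = None) -> ClusterPartition:
    """Load a cluster partition from YAML config text.

    Expected layout::

        clusters:
          Bhutanese: [Bhutan-09015, ...]
          Indonesian: [...]
        subclusters:            # optional
          Indonesian:
            subcluster1: [...]
            subcluster2: [...]

    When ``matrix`` is given the partition is cross-validated against its
    accession set.
    """
    cfg = yaml.safe_load(source)
    if not isinstance(cfg, dict) or "clusters" not in cfg:
        raise PartitionError("config must contain a 'clusters' mapping")
    clusters = cfg["clusters"]
    if not isinstance(clusters, dict) or len(clusters) != 2:
        raise PartitionError(
            f"exactly 2 clusters required, got {len(clusters) if isinstance(clusters, dict) else 0}"
        )
    cluster_of: dict[str, str] = {}
    for label, members in clusters.items():
        if not members:
            raise PartitionError(f"cluster {label!r} is empty")
        for acc in members:
            if acc in cluster_of:
                raise PartitionError(f"accession {acc!r} assigned twice")
            cluster_of[str(acc)] = str(label)
    sub_cfg = cfg.get("subclusters") or {}
    subclustered = None
    sub_order = None
    sub_of: dict[str, str] = {}
    if sub_cfg:
        if len(sub_cfg) != 1:
            raise PartitionError("subclusters may be declared for exactly one cluster")
        subclustered = str(next(iter(sub_cfg)))
        subs = sub_cfg[subclustered]
        if not isinstance(subs, dict) or len(subs) != 2:
            raise PartitionError("exactly 2 subclusters required")
        sub_order = tuple(str(k) for k in subs)
        for label, members in subs.items():
            for acc in members or []:
                if acc in sub_of:
                    raise PartitionError(f"accession {acc!r} in two subclusters")
                sub_of[str(acc)] = str(label)
    part = ClusterPartition(
        cluster_order=tuple(str(k) for k in clusters),
        cluster_of=cluster_of,
        subclustered_cluster=subclustered,
        subcluster_order=sub_order,
        subcluster_of=sub_of,
    )
    if matrix is not None:
        part.validate_against(matrix.accession_ids)
    return part


#: accession ids of the shipped eight-accession lime panel, matrix order
DEFAULT_ACCESSIONS: tuple[str, ...] = (
    "Bhutan-09015",
    "Bhutan-09024",
    "Bhutan-09027",
    "Bhutan-09030",
    "Bhutan-09005",
    "Indonesia-88065",
    "Indonesia-88035",
    "Indonesia-88045",
)


def default_partition() -> ClusterPartition:
    """The shipped lime grouping: a Bhutanese cluster of four accessions
    and an Indonesian cluster of four (one of them collected in Bhutan),
    the latter split into subcluster 1 (Bhutan-09005, Indonesia-88065)
    and subcluster 2 (Indonesia-88035, Indonesia-88045)."""
    from importlib.resources import files

    text = files("limerad.data").joinpath("lime_clusters.yaml").read_text()
    return load_partition(text)
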