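"""End-to-end orchestration: filter -> classify -> stats -> subpatterns -> tree.

A single :class:`RunConfig` drives the whole analysis and produces a
:class:`ReportBundle` plus on-disk artifacts.  The canonical report is
JSON (sorted keys, no timestamps, so a rerun with the same config and
seed is byte-identical); TSVs mirroring the summary-table layouts are
written alongside for human diffing, and run metadata (timestamp,
versions, config hash) is segregated into its own file so determinism
checks can ignore it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import CategoryReport, classify_matrix
from .io import GenotypeMatrix, default_partition, load_partition, parse_alignment
from .phylo import build_tree
from .stats import (
    cluster_identity_counts,
    het_stats,
    pairwise_matches,
    subpattern_table,
    total_bases as _total_bases,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    alignment: str
    format: str = "fasta"
    partition: str | None = None  # path to YAML; None -> shipped lime grouping
    out_dir: str = "limerad_out"
    total_bases: int | None = None
    n_loci: int | None = None
    read_length: int | None = None
    seed: int = 0
    match_categories: list[str] = field(default_factory=lambda: ["E"])
    subpattern_categories: list[str] = field(default_factory=lambda: ["E", "G"])
    tree: bool = True
    tree_metric: str = "mismatch"
    bootstrap: int = 100

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_total_bases(self) -> int | None:
        """Reconcile the two parameterizations of the analyzed-base count."""
        derived = None
        if self.n_loci is not None or self.read_length is not None:
            if self.n_loci is None or self.read_length is None:
                raise ValueError("n_loci and read_length must be given together")
            derived = _total_bases(self.n_loci, self.read_length)
        if self.total_bases is not None and derived is not None:
            if self.total_bases != derived:
                raise ValueError(
                    f"total_bases={self.total_bases} inconsistent with "
                    f"n_loci*read_length={derived}"
                )
        return self.total_bases if self.total_bases is not None else derived

    def digest(self) -> str:
        # out_dir is presentation, not analysis: reruns into different
        # directories must stay byte-identical
        fields = sorted(set(self.__dataclass_fields__) - {"out_dir"})
        payload = json.dumps({k: getattr(self, k) for k in fields}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    report: CategoryReport
    filtered: GenotypeMatrix
    het_table: pd.DataFrame | None
    matches: dict[str, pd.DataFrame]
    subpatterns: dict[str, dict]
    identity_counts: dict[str, dict]
    newick: str | None
    config_digest: str

    def to_json(self) -> str:
        doc = {
            "categories": self.report.to_dict(),
            "het_stats": (
                self.het_table.reset_index().to_dict(orient="records")
                if self.het_table is not None
                else None
            ),
            "matches": {
                cat: df.to_dict(orient="index") for cat, df in self.matches.items()
            },
            "subpatterns": self.subpatterns,
            "identity_counts": self.identity_counts,
            "tree_newick": self.newick,
            "config_digest": self.config_digest,
        }
        return json.dumps(doc, sort_keys=True, indent=2, default=int)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all enabled stages in dependency order and write the
    artifact bundle under ``config.out_dir``."""
    tb = config.resolve_total_bases()  # early validation

    @_stage("load")
    def load():
        text = Path(config.alignment).read_text()
        matrix = parse_alignment(text, config.format)
        if config.partition:
            part = load_partition(Path(config.partition).read_text(), matrix)
        else:
            part = default_partition()
            part.validate_against(matrix.accession_ids)
        return matrix, part

    matrix, partition = load()

    @_stage("classify")
    def do_classify():
        return classify_matrix(matrix, partition)

    report, filtered = do_classify()

    @_stage("stats")
    def do_stats():
        het = het_stats(filtered, tb) if tb else None
        ident = {}
        groups = list(partition.cluster_order)
        if partition.subcluster_order:
            groups += list(partition.subcluster_order)
        for g in groups:
            same, diff = cluster_identity_counts(filtered, partition, g)
            ident[g] = {"identical": same, "non_identical": diff}
        return het, ident

    het_table, identity = do_stats()

    @_stage("matches")
    def do_matches():
        out = {}
        for cat in config.match_categories:
            sites = [i for i, lab in enumerate(report.per_site) if lab == cat]
            group = (
                partition.members(partition.subclustered_cluster)
                if partition.subclustered_cluster
                else None
            )
            out[cat] = pairwise_matches(filtered, sites, group)
        return out

    matches = do_matches()

    @_stage("subpatterns")
    def do_subpatterns():
        out = {}
        if partition.subcluster_order:
            for cat in config.subpattern_categories:
                tab = subpattern_table(filtered, partition, report, cat)
                out[cat] = {
                    "rows": tab.rows.to_dict(orient="records"),
                    "remainder_count": tab.remainder_count,
                    "sub1_het_sub2_hom": tab.sub1_het_sub2_hom,
                    "sub1_hom_sub2_het": tab.sub1_hom_sub2_het,
                }
        return out

    subpatterns = do_subpatterns()

    newick = None
    if config.tree:

        @_stage("tree")
        def do_tree():
            return build_tree(
                filtered,
                metric=config.tree_metric,
                bootstrap=config.bootstrap,
                seed=config.seed,
            )

        newick = do_tree()

    bundle = ReportBundle(
        report=report,
        filtered=filtered,
        het_table=het_table,
        matches=matches,
        subpatterns=subpatterns,
        identity_counts=identity,
        newick=newick,
        config_digest=config.digest(),
    )
    _write_artifacts(bundle, config)
    return bundle


@_stage("write")
def _write_artifacts(bundle: ReportBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(bundle.to_json() + "\n")

    per_site = pd.DataFrame(
        bundle.filtered.calls, columns=bundle.filtered.accession_ids
    )
    per_site.insert(0, "site_index", bundle.report.kept_sites)
    if bundle.filtered.site_ids:
        per_site.insert(1, "site_id", bundle.filtered.site_ids)
    per_site["category"] = bundle.report.per_site
    per_site.to_csv(out / "sites.tsv", sep="\t", index=False)

    if bundle.het_table is not None:
        bundle.het_table.to_csv(out / "het_stats.tsv", sep="\t")
    for cat, df in bundle.matches.items():
        df.to_csv(out / f"matches_{cat}.tsv", sep="\t")
    for cat, tab in bundle.subpatterns.items():
        pd.DataFrame(tab["rows"]).to_csv(
            out / f"subpatterns_{cat}.tsv", sep="\t", index=False
        )
    if bundle.newick:
        (out / "tree.nwk").write_text(bundle.newick + "\n")

    meta = {
        "limerad_version": __version__,
        "config_digest": bundle.config_digest,
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "n_sites_total": bundle.report.n_sites_total,
        "n_sites_genotypable": bundle.report.n_sites_genotypable,
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
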