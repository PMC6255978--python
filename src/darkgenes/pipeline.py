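"""End-to-end orchestration from a single run configuration.

``run_all`` executes every stage — DEG calling, darkness classification,
interactome profiling, literature counting, regulon/signature consensus,
cross-species joining, evidence integration — and writes a report bundle
of TSV tables mirroring the shapes a coverage-audit study publishes:
per-compound DEG counts, biotype tallies, coverage percentages, degree and
top-connected tables, literature top tables, mapping overview, consensus +
Venn regions, ortholog-pathology rows and evidence summaries.

The bundle is deterministic: rerunning on the same inputs reproduces it
byte for byte (the run log records seed, policies and versions but no
timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    AnnotationUniverse,
    classify_darkness,
    coverage_report,
    dark_set,
    parse_gmt,
    parse_go_annotations,
    parse_omnipath,
    parse_pathway_commons,
    tally_biotypes,
)
from .diffexpr import DEGParams, ExpressionMatrix, call_degs, deg_sets, union_group_degs
from .evidence import (
    TierParams,
    build_evidence_matrix,
    coverage_fraction,
    exclusivity_flags,
    score_and_tier,
)
from .idmap import GeneCatalog, load_gene_catalog
from .interactome import (
    degree_profile,
    load_edge_list,
    per_snapshot_presence,
    presence_summary,
    top_connected,
)
from .literature import evidence_count_table
from .regulon_pathway import (
    consensus_sets,
    load_regulon_table,
    load_signature_table,
    map_regulators,
    mapping_overview,
)
from .xspecies import (
    ModuleContext,
    assign_modules,
    load_ortholog_table,
    map_orthologs,
    pathology_report,
)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "deg_counts.tsv",
    "biotype_table.tsv",
    "coverage.tsv",
    "degree_table.tsv",
    "top_connected.tsv",
    "literature_counts.tsv",
    "mapping_overview.tsv",
    "consensus_venn.tsv",
    "ortholog_pathology.tsv",
    "evidence_summary.tsv",
)


@dataclass
class RunConfig:
    """Paths to every input plus analysis policies."""

    indir: Path
    outdir: Path
    deg_params: DEGParams = field(default_factory=DEGParams)
    tier_params: TierParams = field(default_factory=TierParams)
    empty_policy: str = "exclude_empty"
    rank_statistic: str = "max_degree"
    top_k: int = 10
    generif_highlight: int = 10
    drop_predicted_snapshots: tuple[str, ...] = ("INBIOMAP",)
    snapshot_names: tuple[str, ...] = ("BIANA", "HIPPIE", "INBIOMAP", "INTACT")
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        deg = DEGParams(**data.pop("deg_params", {}))
        tier = TierParams(**data.pop("tier_params", {}))
        for key in ("drop_predicted_snapshots", "snapshot_names"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(
            indir=Path(data.pop("indir")),
            outdir=Path(data.pop("outdir")),
            deg_params=deg,
            tier_params=tier,
            **data,
        )

    def to_dict(self) -> dict:
        return {
            "indir": str(self.indir),
            "outdir": str(self.outdir),
            "deg_params": vars(self.deg_params),
            "tier_params": vars(self.tier_params),
            "empty_policy": self.empty_policy,
            "rank_statistic": self.rank_statistic,
            "top_k": self.top_k,
            "generif_highlight": self.generif_highlight,
            "drop_predicted_snapshots": list(self.drop_predicted_snapshots),
            "snapshot_names": list(self.snapshot_names),
            "seed": self.seed,
        }


@dataclass
class RunResult:
    """In-memory handles on everything the bundle serializes."""

    catalog: GeneCatalog
    deg_tables: dict[str, pd.DataFrame]
    groups: dict[str, str]
    universe: AnnotationUniverse
    dark_calls: list
    background_calls: list
    degree_table: pd.DataFrame
    evidence_matrix: pd.DataFrame
    evidence_summary: pd.DataFrame
    outdir: Path


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage and write the report bundle."""
    indir, outdir = Path(config.indir), Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = _load_catalog(indir)
    matrix, groups = _load_expression(indir)
    deg_tables = _call_all_degs(matrix, config.deg_params)
    union = union_group_degs(deg_tables, groups)

    universe = _build_universe(indir, catalog)
    dark_calls = classify_darkness(union.overall, universe)
    background_calls = classify_darkness(catalog.entrez_ids, universe)
    dark = dark_set(dark_calls)
    dark_by_compound = {c: s & dark for c, s in deg_sets(deg_tables).items()}

    snapshots = _load_snapshots(indir, catalog, config)
    degree_table = degree_profile(dark, snapshots)

    lit = evidence_count_table(
        indir / "disease.tsv", indir / "generif.tsv", indir / "gene2pub.tsv", genes=dark
    )

    regulons = load_regulon_table(indir / "regulons.tsv")
    signatures = load_signature_table(indir / "signatures.tsv")
    reg_map = map_regulators(dark_by_compound, regulons)
    sig_map = map_regulators(dark_by_compound, signatures)

    ortho = map_orthologs(dark, load_ortholog_table(indir / "orthologs.tsv"))
    context = ModuleContext.from_files(indir / "modules.tsv", indir / "module_annotations.tsv")
    assignment = assign_modules(ortho.rat_genes, context)

    ev_matrix = build_evidence_matrix(
        dark_calls, degree_table, lit, reg_map, sig_map, ortho, assignment
    )
    summary = score_and_tier(ev_matrix, config.tier_params)
    excl = exclusivity_flags(deg_tables, groups, sorted(dark))
    summary = summary.join(excl[["most_dili_exclusive", "deg_in_4of5_dili"]])

    _write_bundle(
        config, outdir, catalog, deg_tables, groups, union, dark_calls, background_calls,
        degree_table, lit, dark_by_compound, reg_map, sig_map, ortho, assignment, context,
        ev_matrix, summary,
    )
    return RunResult(
        catalog=catalog,
        deg_tables=deg_tables,
        groups=groups,
        universe=universe,
        dark_calls=dark_calls,
        background_calls=background_calls,
        degree_table=degree_table,
        evidence_matrix=ev_matrix,
        evidence_summary=summary,
        outdir=outdir,
    )


@_stage("catalog")
def _load_catalog(indir: Path) -> GeneCatalog:
    return load_gene_catalog(
        indir / "gene_info.tsv",
        biotype_table=indir / "biotypes.tsv",
        hgnc_table=indir / "hgnc.tsv",
    )


@_stage("expression")
def _load_expression(indir: Path) -> tuple[ExpressionMatrix, dict[str, str]]:
    matrix = ExpressionMatrix.from_files(indir / "expression.tsv", indir / "sample_meta.tsv")
    groups = (
        matrix.sample_meta.drop_duplicates("compound").set_index("compound")["group"].to_dict()
    )
    return matrix, groups


@_stage("diffexpr")
def _call_all_degs(matrix: ExpressionMatrix, params: DEGParams) -> dict[str, pd.DataFrame]:
    return {c: call_degs(matrix, c, params) for c in matrix.compounds()}


@_stage("annotation")
def _build_universe(indir: Path, catalog: GeneCatalog) -> AnnotationUniverse:
    return AnnotationUniverse(
        resources=[
            parse_go_annotations(indir / "go_annotations.tsv", catalog),
            parse_gmt(indir / "reactome.gmt", catalog, name="Reactome"),
            parse_gmt(indir / "msigdb.gmt", catalog, name="MSigDB"),
            parse_pathway_commons(indir / "pathway_commons.tsv", catalog),
            parse_omnipath(indir / "omnipath.tsv", catalog),
        ]
    )


@_stage("interactome")
def _load_snapshots(indir: Path, catalog: GeneCatalog, config: RunConfig):
    return [
        load_edge_list(
            indir / f"edges_{name}.tsv",
            catalog,
            name,
            drop_predicted=name in config.drop_predicted_snapshots,
        )
        for name in config.snapshot_names
    ]


def _write_bundle(
    config: RunConfig,
    outdir: Path,
    catalog: GeneCatalog,
    deg_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    union,
    dark_calls,
    background_calls,
    degree_table: pd.DataFrame,
    lit: pd.DataFrame,
    dark_by_compound,
    reg_map,
    sig_map,
    ortho,
    assignment,
    context,
    ev_matrix: pd.DataFrame,
    summary: pd.DataFrame,
) -> None:
    # Table-1 shape: per-compound DEG counts with group totals
    rows = [
        {"compound": c, "group": groups[c], "n_deg": union.per_compound_counts[c]}
        for c in sorted(deg_tables)
    ]
    for grp, genes in sorted(union.per_group.items()):
        rows.append({"compound": f"total_{grp}", "group": grp, "n_deg": len(genes)})
    rows.append({"compound": "total_unique", "group": "all", "n_deg": len(union.overall)})
    pd.DataFrame(rows).to_csv(outdir / "deg_counts.tsv", sep="\t", index=False)

    # Table-2 shape: biotype tallies
    group_membership = {g: union.per_group[g] for g in sorted(union.per_group)}
    tally = tally_biotypes(dark_calls, catalog, group_membership)
    tally.to_csv(outdir / "biotype_table.tsv", sep="\t", index_label="biotype")

    # coverage percentages, both display conventions
    fg, bg = coverage_report(dark_calls, background_calls)
    frac, floor_pct = coverage_fraction(ev_matrix) if not ev_matrix.empty else (0.0, 0)
    pd.DataFrame(
        [
            ("dark_degs", fg.n_dark, fg.n_input, round(fg.dark_fraction, 1), fg.percent_rounded, fg.percent_floor),
            ("array_background", bg.n_dark, bg.n_input, round(bg.dark_fraction, 1), bg.percent_rounded, bg.percent_floor),
            ("dark_with_evidence", int(round(frac * fg.n_dark)), fg.n_dark, round(100 * frac, 1), int(frac * 100 + 0.5), floor_pct),
        ],
        columns=["set", "n_dark_or_hit", "n_total", "percent_raw", "percent_rounded", "percent_floor"],
    ).to_csv(outdir / "coverage.tsv", sep="\t", index=False)

    degree_table.to_csv(outdir / "degree_table.tsv", sep="\t", float_format="%.0f")
    ge1, in_all = presence_summary(degree_table)
    per_snap = per_snapshot_presence(degree_table)
    with open(outdir / "degree_table.tsv", "a") as fh:
        fh.write(f"# present_in_ge1\t{ge1}\n# present_in_all\t{in_all}\n")
        for name, count in sorted(per_snap.items()):
            fh.write(f"# present_{name}\t{count}\n")

    top_connected(degree_table, config.top_k, config.rank_statistic).to_csv(
        outdir / "top_connected.tsv", sep="\t", float_format="%.0f"
    )

    lit_out = lit.copy()
    lit_out["generif_highlight"] = lit_out["n_generifs"] >= config.generif_highlight
    lit_out.to_csv(outdir / "literature_counts.tsv", sep="\t")

    # Table-6 shape
    mapping_overview(dark_by_compound, reg_map, sig_map).to_csv(outdir / "mapping_overview.tsv", sep="\t")

    # Fig-2 shape: consensus + Venn regions per group and table kind
    venn_rows = []
    for kind, mappings in (("TF", reg_map), ("pathway", sig_map)):
        for grp in sorted(set(groups.values())):
            members = [m for m in mappings if groups[m.compound] == grp]
            res = consensus_sets(members, config.empty_policy, group=grp)
            strict = consensus_sets(members, "strict", group=grp)
            venn_rows.append(
                {
                    "kind": kind,
                    "group": grp,
                    "policy": config.empty_policy,
                    "consensus": ";".join(sorted(res.consensus)),
                    "consensus_strict": ";".join(sorted(strict.consensus)),
                    "venn_regions": ";".join(
                        f"{'&'.join(sorted(k))}={v}" for k, v in sorted(
                            res.venn_region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
                        )
                    ),
                }
            )
    pd.DataFrame(venn_rows).to_csv(outdir / "consensus_venn.tsv", sep="\t", index=False)

    # Table-7 shape
    pathology_report(assignment, context).to_csv(outdir / "ortholog_pathology.tsv", sep="\t", index=False)

    out = ev_matrix.astype(int).join(summary)
    out.to_csv(outdir / "evidence_summary.tsv", sep="\t")

    # no paths or timestamps in the log: the bundle must be byte-identical
    # across reruns on the same inputs wherever it is written
    policies = {k: v for k, v in config.to_dict().items() if k not in ("indir", "outdir")}
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "policies": policies,
        "n_dark_genes": len(dark_set(dark_calls)),
        "report_files": list(REPORT_FILES),
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
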