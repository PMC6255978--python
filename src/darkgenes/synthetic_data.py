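"""Seeded synthetic world emulating every pipeline input.

One call to :func:`simulate_world` writes a complete fixture bundle — gene
catalog, five annotation resources, four interaction edge lists, three
literature tables, regulon and signature tables, ortholog/module/pathology
tables, and a log2 expression matrix with metadata — plus the ground truth
(planted dark genes, per-compound planted DEGs, planted group-consensus
regulators) needed to verify recovery.

Planted structure honors three guarantees:

- planted dark genes appear in **zero** annotation resources;
- every other gene appears in **at least one** resource;
- each planted group-consensus TF/pathway targets ≥1 planted dark DEG of
  **every** compound in its group, so a strict group intersection must
  recover it.

Randomness comes from one seed split into named substreams, one per
artifact file, so adding an output never perturbs the others; identical
config and seed give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .idmap import BIOTYPES

SNAPSHOT_NAMES = ("BIANA", "HIPPIE", "INBIOMAP", "INTACT")

PATHOLOGY_LABELS = (
    "BDH",
    "Fibrosis",
    "Necrosis",
    "Hypertrophy",
    "Adverse at 29 days",
    "Increased mitosis",
    "Single cell necrosis",
    "Vacuolation",
)

GO_BP_LABELS = (
    "Inflammatory response",
    "Cell cycle",
    "Extracellular matrix organization",
    "Protein folding",
    "Signal transduction",
    "Lipid metabolic process",
    "Response to oxidative stress",
    "Apoptotic process",
)


def _default_biotype_proportions() -> dict[str, float]:
    return {
        "protein_coding": 0.70,
        "antisense": 0.07,
        "lincRNA": 0.08,
        "processed_transcript": 0.03,
        "pseudogene": 0.05,
        "snoRNA": 0.01,
        "sense_intronic": 0.01,
        "sense_overlapping": 0.005,
        "miRNA": 0.005,
        "TEC": 0.01,
        "unknown": 0.03,
    }


def _default_annotation_coverage() -> dict[str, float]:
    return {
        "GO_BP": 0.85,
        "Reactome": 0.50,
        "MSigDB": 0.60,
        "PathwayCommons": 0.70,
        "OmniPath": 0.40,
    }


@dataclass
class WorldConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 2000
    first_entrez: int = 1001
    biotype_proportions: dict[str, float] = field(default_factory=_default_biotype_proportions)
    annotation_coverage: dict[str, float] = field(default_factory=_default_annotation_coverage)
    n_planted_dark: int = 200
    compounds_most_dili: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")
    compounds_no_dili: tuple[str, ...] = ("N1", "N2", "N3", "N4", "N5")
    # differential-expression model
    n_deg_per_compound: int = 300
    n_dark_deg_per_compound: int = 60
    effect_size_mean: float = 1.2
    effect_size_sd: float = 0.0
    noise_sd: float = 0.25
    n_replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # interactome model
    edges_per_snapshot: int = 6000
    snapshot_node_fraction: float = 0.7
    degree_tail_exponent: float = 0.9
    predicted_edge_fraction: float = 0.1  # INBIOMAP only
    # regulon / signature model
    n_tfs: int = 40
    targets_per_tf: int = 25
    n_consensus_tfs_per_group: int = 3
    n_pathways: int = 12
    genes_per_pathway: int = 30
    n_consensus_pathways_per_group: int = 2
    # literature model
    disease_gene_prob: float = 0.30
    disease_rate: float = 2.0
    curated_row_prob: float = 0.40
    generif_gene_prob: float = 0.35
    generif_rate: float = 3.0
    pub_gene_prob: float = 0.50
    pub_rate: float = 4.0
    # cross-species model
    ortholog_rate: float = 0.6
    one_to_many_prob: float = 0.05
    n_modules: int = 25
    module_member_prob: float = 0.5
    pathology_label_prob: float = 0.5
    go_bp_label_prob: float = 0.6

    def validate(self) -> None:
        for name, probs in (("biotype_proportions", self.biotype_proportions.values()),
                            ("annotation_coverage", self.annotation_coverage.values())):
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_planted_dark > self.n_genes:
            raise ValueError("n_planted_dark cannot exceed n_genes")
        if self.n_dark_deg_per_compound > self.n_planted_dark:
            raise ValueError("n_dark_deg_per_compound cannot exceed n_planted_dark")
        if self.n_deg_per_compound > self.n_genes:
            raise ValueError("n_deg_per_compound cannot exceed n_genes")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    @property
    def groups(self) -> dict[str, str]:
        out = {c: "most_dili" for c in self.compounds_most_dili}
        out.update({c: "no_dili" for c in self.compounds_no_dili})
        return out

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self.compounds_most_dili) + tuple(self.compounds_no_dili)


@dataclass
class WorldTruth:
    """Planted ground truth of one simulated world."""

    planted_dark: set[int]
    deg_sets: dict[str, set[int]]            # compound -> planted DEG genes
    deg_effects: dict[str, dict[int, float]]  # compound -> gene -> signed log2 effect
    consensus_tfs: dict[str, set[str]]        # group -> planted consensus TFs
    consensus_pathways: dict[str, set[str]]
    pathology_module_genes: set[str]          # rat genes in pathology-linked modules
    groups: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "planted_dark": sorted(self.planted_dark),
            "deg_sets": {c: sorted(s) for c, s in sorted(self.deg_sets.items())},
            "deg_effects": {
                c: {str(g): e for g, e in sorted(eff.items())}
                for c, eff in sorted(self.deg_effects.items())
            },
            "consensus_tfs": {g: sorted(s) for g, s in sorted(self.consensus_tfs.items())},
            "consensus_pathways": {g: sorted(s) for g, s in sorted(self.consensus_pathways.items())},
            "pathology_module_genes": sorted(self.pathology_module_genes),
            "groups": dict(sorted(self.groups.items())),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorldTruth":
        d = json.loads(text)
        return cls(
            planted_dark=set(d["planted_dark"]),
            deg_sets={c: set(v) for c, v in d["deg_sets"].items()},
            deg_effects={c: {int(g): e for g, e in eff.items()} for c, eff in d["deg_effects"].items()},
            consensus_tfs={g: set(v) for g, v in d["consensus_tfs"].items()},
            consensus_pathways={g: set(v) for g, v in d["consensus_pathways"].items()},
            pathology_module_genes=set(d["pathology_module_genes"]),
            groups=d["groups"],
        )


def _rng(config: WorldConfig, stream: str) -> np.random.Generator:
    # named substream: stable per-artifact child seed independent of other files
    return np.random.default_rng([zlib.crc32(stream.encode()) % (2**31), config.seed % (2**31)])


def _symbol(eid: int) -> str:
    return f"G{eid}"


def simulate_world(config: WorldConfig, outdir: str | Path) -> tuple[dict[str, Path], WorldTruth]:
    """Write the full fixture bundle under ``outdir``; return paths + truth."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = np.arange(config.first_entrez, config.first_entrez + config.n_genes)

    # --- biotypes and catalog ------------------------------------------------
    rng = _rng(config, "catalog")
    labels = [b for b in BIOTYPES if b in config.biotype_proportions]
    probs = np.array([config.biotype_proportions[b] for b in labels], float)
    probs = probs / probs.sum()
    biotypes = rng.choice(labels, size=config.n_genes, p=probs)

    paths: dict[str, Path] = {}

    gene_info = pd.DataFrame(
        {
            "tax_id": 9606,
            "GeneID": genes,
            "Symbol": [_symbol(g) for g in genes],
            "Synonyms": [f"S{g}|ALT{g}" for g in genes],
        }
    )
    paths["gene_info"] = _write(outdir / "gene_info.tsv", gene_info)
    paths["biotypes"] = _write(outdir / "biotypes.tsv", pd.DataFrame({"entrez": genes, "biotype": biotypes}))
    paths["hgnc"] = _write(
        outdir / "hgnc.tsv",
        pd.DataFrame({"entrez_id": genes, "uniprot_ids": [f"Q{g:06d}" for g in genes]}),
    )

    # --- planted dark set and resource membership ----------------------------
    rng = _rng(config, "darkness")
    planted_dark = set(int(g) for g in rng.choice(genes, config.n_planted_dark, replace=False))
    annotated = np.array([g for g in genes if g not in planted_dark])
    membership: dict[str, set[int]] = {name: set() for name in config.annotation_coverage}
    resource_names = sorted(config.annotation_coverage)
    for gene in annotated:
        hit = False
        for name in resource_names:
            if rng.random() < config.annotation_coverage[name]:
                membership[name].add(int(gene))
                hit = True
        if not hit:  # guarantee: non-planted genes are annotated somewhere
            membership[max(config.annotation_coverage, key=config.annotation_coverage.get)].add(int(gene))

    paths.update(_write_annotation_files(config, outdir, genes, planted_dark, membership))

    # --- differential expression truth --------------------------------------
    rng = _rng(config, "degs")
    deg_sets: dict[str, set[int]] = {}
    deg_effects: dict[str, dict[int, float]] = {}
    dark_sorted = np.array(sorted(planted_dark))
    annotated_sorted = np.array(sorted(set(map(int, annotated))))
    for compound in config.compounds:
        n_dark = config.n_dark_deg_per_compound
        dark_part = rng.choice(dark_sorted, n_dark, replace=False) if n_dark else np.array([], int)
        n_rest = config.n_deg_per_compound - n_dark
        rest = rng.choice(annotated_sorted, n_rest, replace=False) if n_rest else np.array([], int)
        members = sorted(set(map(int, dark_part)) | set(map(int, rest)))
        deg_sets[compound] = set(members)
        effects = {}
        for gene in members:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            magnitude = config.effect_size_mean + config.effect_size_sd * rng.standard_normal()
            effects[gene] = float(sign * magnitude)
        deg_effects[compound] = effects

    # --- regulons and signatures ---------------------------------------------
    truth_tfs, regulon_rows = _plant_regulators(
        config, "regulons", [f"TF{i:02d}" for i in range(1, config.n_tfs + 1)],
        config.targets_per_tf, config.n_consensus_tfs_per_group,
        genes, planted_dark, deg_sets,
    )
    reg_df = pd.DataFrame(regulon_rows, columns=["tf", "target", "grade"])
    paths["regulons"] = _write(outdir / "regulons.tsv", reg_df)

    truth_pathways, signature_rows = _plant_regulators(
        config, "signatures", [f"PW{i:02d}" for i in range(1, config.n_pathways + 1)],
        config.genes_per_pathway, config.n_consensus_pathways_per_group,
        genes, planted_dark, deg_sets, with_grade=False,
    )
    sig_df = pd.DataFrame(signature_rows, columns=["pathway", "gene"])
    paths["signatures"] = _write(outdir / "signatures.tsv", sig_df)

    # --- interactomes ---------------------------------------------------------
    for name in SNAPSHOT_NAMES:
        paths[f"edges_{name}"] = _write(
            outdir / f"edges_{name}.tsv", _simulate_edges(config, name, genes)
        )

    # --- literature -----------------------------------------------------------
    paths.update(_write_literature(config, outdir, genes))

    # --- orthologs, modules, pathology ---------------------------------------
    ortho_paths, pathology_module_genes = _write_xspecies(config, outdir, genes)
    paths.update(ortho_paths)

    # --- expression -----------------------------------------------------------
    expr_paths = _write_expression(config, outdir, genes, deg_effects)
    paths.update(expr_paths)

    truth = WorldTruth(
        planted_dark=planted_dark,
        deg_sets=deg_sets,
        deg_effects=deg_effects,
        consensus_tfs=truth_tfs,
        consensus_pathways=truth_pathways,
        pathology_module_genes=pathology_module_genes,
        groups=config.groups,
    )
    truth_path = outdir / "truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    paths["truth"] = truth_path
    paths["manifest"] = _write_manifest(outdir, paths)
    return paths, truth


def _write(path: Path, frame: pd.DataFrame) -> Path:
    frame.to_csv(path, sep="\t", index=False)
    return path


def _write_manifest(outdir: Path, paths: Mapping[str, Path]) -> Path:
    rows = []
    for key in sorted(paths):
        digest = hashlib.sha256(paths[key].read_bytes()).hexdigest()
        rows.append(f"{paths[key].name}\t{digest}")
    manifest = outdir / "MANIFEST.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def _write_annotation_files(
    config: WorldConfig,
    outdir: Path,
    genes: np.ndarray,
    planted_dark: set[int],
    membership: dict[str, set[int]],
) -> dict[str, Path]:
    paths = {}
    rng = _rng(config, "annotation_files")

    # GO: aspect-P rows only for GO_BP members; dark genes may still carry
    # molecular-function / cellular-component rows.
    go_rows = []
    for gene in sorted(membership["GO_BP"]):
        for term in range(rng.integers(1, 4)):
            go_rows.append((_symbol(gene), f"GO:{7000 + term:07d}", "P"))
    for gene in sorted(genes):
        if rng.random() < 0.3:
            go_rows.append((_symbol(gene), f"GO:{3000:07d}", rng.choice(["F", "C"])))
    paths["go"] = _write(outdir / "go_annotations.tsv", pd.DataFrame(go_rows, columns=["gene", "go_term", "aspect"]))

    # GMT resources: partition members into sets of ~25
    for name, fname in (("Reactome", "reactome.gmt"), ("MSigDB", "msigdb.gmt")):
        members = sorted(membership[name])
        rng.shuffle(members)
        lines = []
        for i in range(0, len(members), 25):
            chunk = members[i : i + 25]
            lines.append("\t".join([f"{name}_SET_{i // 25 + 1}", "synthetic gene set"] + [_symbol(g) for g in chunk]))
        (outdir / fname).write_text("\n".join(lines) + "\n")
        paths[name.lower()] = outdir / fname

    # Pathway Commons: pathway-annotated rows carry members; decoy rows with
    # an empty pathway field may involve any gene, including dark ones.
    pc_members = sorted(membership["PathwayCommons"])
    pc_rows = []
    for i in range(0, len(pc_members) - 1, 2):
        pc_rows.append((_symbol(pc_members[i]), _symbol(pc_members[i + 1]), f"PC_PATH_{i // 2 + 1}"))
    for _ in range(len(pc_members) // 4):
        a, b = rng.choice(genes, 2, replace=False)
        pc_rows.append((_symbol(int(a)), _symbol(int(b)), ""))
    paths["pathway_commons"] = _write(
        outdir / "pathway_commons.tsv",
        pd.DataFrame(pc_rows, columns=["participant_a", "participant_b", "pathway"]),
    )

    # OmniPath: kept rows cite a signaling source; decoy rows citing only
    # pure-PPI databases may involve any gene.
    op_members = sorted(membership["OmniPath"])
    op_rows = []
    signal_sources = ["SIGNOR", "KEGG", "SignaLink"]
    for i in range(0, len(op_members) - 1, 2):
        src = signal_sources[(i // 2) % len(signal_sources)]
        extra = ";BioGRID" if rng.random() < 0.3 else ""
        op_rows.append((_symbol(op_members[i]), _symbol(op_members[i + 1]), src + extra))
    for _ in range(len(op_members) // 4):
        a, b = rng.choice(genes, 2, replace=False)
        ppi = rng.choice(["BioGRID", "HPRD", "IntAct", "BioGRID;IntAct"])
        op_rows.append((_symbol(int(a)), _symbol(int(b)), ppi))
    paths["omnipath"] = _write(
        outdir / "omnipath.tsv", pd.DataFrame(op_rows, columns=["source", "target", "sources"])
    )
    return paths


def _plant_regulators(
    config: WorldConfig,
    stream: str,
    names: list[str],
    targets_per: int,
    n_consensus_per_group: int,
    genes: np.ndarray,
    planted_dark: set[int],
    deg_sets: dict[str, set[int]],
    with_grade: bool = True,
):
    rng = _rng(config, stream)
    group_compounds = {
        "most_dili": list(config.compounds_most_dili),
        "no_dili": list(config.compounds_no_dili),
    }
    consensus: dict[str, set[str]] = {g: set() for g in group_compounds}
    pool = list(names)
    for group in sorted(group_compounds):
        for _ in range(n_consensus_per_group):
            consensus[group].add(pool.pop(0))

    targets: dict[str, set[int]] = {}
    for name in names:
        targets[name] = set(map(int, rng.choice(genes, targets_per, replace=False)))
    # guarantee: each consensus regulator of a group covers planted dark
    # DEGs of every compound in that group (several, as real consensus
    # regulators govern many targets per perturbation)
    for group, regs in consensus.items():
        for reg in sorted(regs):
            for compound in group_compounds[group]:
                dark_degs = np.array(sorted(planted_dark & deg_sets[compound]))
                n_pick = min(3, len(dark_degs))
                if n_pick:
                    targets[reg].update(int(g) for g in rng.choice(dark_degs, n_pick, replace=False))
    rows = []
    for name in names:
        for gene in sorted(targets[name]):
            if with_grade:
                rows.append((name, gene, rng.choice(["A", "B", "C", "D"])))
            else:
                rows.append((name, gene))
    return consensus, rows


def _simulate_edges(config: WorldConfig, name: str, genes: np.ndarray) -> pd.DataFrame:
    rng = _rng(config, f"edges_{name}")
    n_nodes = int(config.snapshot_node_fraction * len(genes))
    nodes = rng.choice(genes, n_nodes, replace=False)
    ranks = np.arange(1, n_nodes + 1, dtype=float)
    weights = ranks ** (-config.degree_tail_exponent)
    weights /= weights.sum()
    edges = set()
    attempts = 0
    while len(edges) < config.edges_per_snapshot and attempts < config.edges_per_snapshot * 20:
        a, b = rng.choice(nodes, 2, p=weights)
        attempts += 1
        if a == b:
            continue
        edges.add((min(int(a), int(b)), max(int(a), int(b))))
    rows = [(_symbol(a), _symbol(b)) for a, b in sorted(edges)]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    if name == "INBIOMAP":  # predicted interactions, removed by the loader
        df["predicted"] = (rng.random(len(df)) < config.predicted_edge_fraction).astype(int)
    return df


def _write_literature(config: WorldConfig, outdir: Path, genes: np.ndarray) -> dict[str, Path]:
    rng = _rng(config, "literature")
    disease_rows, rif_rows, pub_rows = [], [], []
    for gene in map(int, genes):
        if rng.random() < config.disease_gene_prob:
            n = 1 + rng.poisson(config.disease_rate)
            for d in range(n):
                tier = "curated" if rng.random() < config.curated_row_prob else "mined"
                disease_rows.append((gene, f"D{rng.integers(1, 400):04d}", tier))
        if rng.random() < config.generif_gene_prob:
            n = 1 + rng.poisson(config.generif_rate)
            for r in range(n):
                rif_rows.append((gene, f"functional statement {r}", int(rng.integers(10_000_000, 35_000_000))))
        if rng.random() < config.pub_gene_prob:
            n = 1 + rng.poisson(config.pub_rate)
            for _ in range(n):
                pub_rows.append((gene, int(rng.integers(10_000_000, 35_000_000))))
    return {
        "disease": _write(outdir / "disease.tsv", pd.DataFrame(disease_rows, columns=["gene", "disease_id", "source_tier"])),
        "generif": _write(outdir / "generif.tsv", pd.DataFrame(rif_rows, columns=["gene", "rif_text", "pmid"])),
        "gene2pub": _write(outdir / "gene2pub.tsv", pd.DataFrame(pub_rows, columns=["gene", "pmid"])),
    }


def _write_xspecies(config: WorldConfig, outdir: Path, genes: np.ndarray) -> tuple[dict[str, Path], set[str]]:
    rng = _rng(config, "xspecies")
    ortho_rows = []
    rat_genes = []
    for gene in map(int, genes):
        if rng.random() < config.ortholog_rate:
            rat = f"r{gene}"
            ortho_rows.append((gene, rat))
            rat_genes.append(rat)
            if rng.random() < config.one_to_many_prob:
                ortho_rows.append((gene, rat + "b"))
                rat_genes.append(rat + "b")
    module_ids = [str(i) for i in range(1, config.n_modules + 1)]
    module_rows = []
    for rat in rat_genes:
        if rng.random() < config.module_member_prob:
            module_rows.append((rat, module_ids[int(rng.integers(config.n_modules))]))
    annot_rows = []
    pathology_modules = set()
    for mod in module_ids:
        if rng.random() < config.pathology_label_prob:
            n_labels = 1 + int(rng.integers(2))
            labels = sorted(rng.choice(PATHOLOGY_LABELS, n_labels, replace=False))
            pathology_modules.add(mod)
            pathology = "; ".join(labels)
        else:
            pathology = ""
        if rng.random() < config.go_bp_label_prob:
            go = "; ".join(sorted(rng.choice(GO_BP_LABELS, 2, replace=False)))
        else:
            go = ""
        annot_rows.append((mod, pathology, go))
    pathology_genes = {rat for rat, mod in module_rows if mod in pathology_modules}
    paths = {
        "orthologs": _write(outdir / "orthologs.tsv", pd.DataFrame(ortho_rows, columns=["human_entrez", "rat_gene"])),
        "modules": _write(outdir / "modules.tsv", pd.DataFrame(module_rows, columns=["rat_gene", "module_id"])),
        "module_annotations": _write(outdir / "module_annotations.tsv", pd.DataFrame(annot_rows, columns=["module_id", "pathology", "go_bp"])),
    }
    return paths, pathology_genes


def _write_expression(
    config: WorldConfig,
    outdir: Path,
    genes: np.ndarray,
    deg_effects: dict[str, dict[int, float]],
) -> dict[str, Path]:
    rng = _rng(config, "expression")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(genes))
    gene_pos = {int(g): i for i, g in enumerate(genes)}
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for compound in config.compounds:
        effect = np.zeros(len(genes))
        for gene, e in deg_effects[compound].items():
            effect[gene_pos[gene]] = e
        for rep in range(1, config.n_replicates + 1):
            sid = f"{compound}_trt_{rep}"
            columns[sid] = baseline + effect + rng.normal(0, config.noise_sd, len(genes))
            meta_rows.append((sid, compound, "high", 24, "treated", config.groups[compound]))
        for rep in range(1, config.n_replicates + 1):
            sid = f"{compound}_ctl_{rep}"
            columns[sid] = baseline + rng.normal(0, config.noise_sd, len(genes))
            meta_rows.append((sid, compound, "high", 24, "control", config.groups[compound]))
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene")).round(4)
    values.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.4f")
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "compound", "dose_level", "time_h", "role", "group"])
    meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    return {"expression": outdir / "expression.tsv", "sample_meta": outdir / "sample_meta.tsv"}


def simulate_expression(config: WorldConfig, truth: WorldTruth, outdir: str | Path) -> dict[str, Path]:
    """Regenerate only the expression matrix + metadata for given truth."""
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = np.arange(config.first_entrez, config.first_entrez + config.n_genes)
    return _write_expression(config, outdir, genes, truth.deg_effects)


def config_from_yaml(path: str | Path) -> WorldConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in WorldConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown world-config keys: {sorted(unknown)}")
    for key in ("compounds_most_dili", "compounds_no_dili"):
        if key in data:
            data[key] = tuple(data[key])
    return WorldConfig(**data)


def config_to_dict(config: WorldConfig) -> dict:
    return asdict(config)
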