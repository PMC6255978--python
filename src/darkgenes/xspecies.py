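"""Cross-species context: rat orthologs, co-expression modules, pathology.

Human dark genes are mapped to rat orthologs (one-to-many mappings kept
and flagged), assigned to published liver co-expression modules, and
joined with the modules' pathology associations and GO-BP labels. Module
construction and module–pathology correlation are upstream published
tables, not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PLACEHOLDER = "-"  # rendered for modules lacking GO-BP labels


def load_ortholog_table(path: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Ortholog TSV with columns ``human_entrez`` and ``rat_gene``."""
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t", dtype=str)
    df = df.drop_duplicates(subset=["human_entrez", "rat_gene"]).copy()
    df["human_entrez"] = df["human_entrez"].astype(int)
    return df


@dataclass
class OrthologMapping:
    per_gene: dict[int, list[str]]
    rat_genes: set[str]
    unmapped: set[int]
    one_to_many: set[int] = field(default_factory=set)

    @property
    def n_mapped(self) -> int:
        return len(self.per_gene)


def map_orthologs(human_genes: Iterable[int], table: pd.DataFrame) -> OrthologMapping:
    """Rat orthologs for each human gene; 1:N mappings retained and flagged."""
    human_genes = set(human_genes)
    sub = table[table["human_entrez"].isin(human_genes)]
    per_gene: dict[int, list[str]] = {}
    for human, group in sub.groupby("human_entrez"):
        per_gene[int(human)] = sorted(group["rat_gene"])
    return OrthologMapping(
        per_gene=per_gene,
        rat_genes=set(sub["rat_gene"]),
        unmapped=human_genes - set(per_gene),
        one_to_many={g for g, rats in per_gene.items() if len(rats) > 1},
    )


@dataclass
class ModuleContext:
    """Module membership plus per-module pathology and GO-BP labels."""

    members: dict[str, set[str]]          # module_id -> rat genes
    pathology: dict[str, list[str]]       # module_id -> pathology labels
    go_bp: dict[str, list[str]]           # module_id -> GO-BP labels

    @classmethod
    def from_files(
        cls,
        module_table: str | Path | pd.DataFrame,
        annotation_table: str | Path | pd.DataFrame,
    ) -> "ModuleContext":
        """module TSV (rat_gene, module_id) + annotation TSV
        (module_id, pathology, go_bp); empty label cells mean none."""
        mt = module_table if isinstance(module_table, pd.DataFrame) else pd.read_csv(module_table, sep="\t", dtype=str)
        at = annotation_table if isinstance(annotation_table, pd.DataFrame) else pd.read_csv(annotation_table, sep="\t", dtype=str)
        members: dict[str, set[str]] = {}
        for mod, group in mt.groupby("module_id"):
            members[str(mod)] = set(group["rat_gene"])
        pathology: dict[str, list[str]] = {}
        go_bp: dict[str, list[str]] = {}
        for _, row in at.iterrows():
            mod = str(row["module_id"])
            pathology[mod] = _split_labels(row.get("pathology"))
            go_bp[mod] = _split_labels(row.get("go_bp"))
        return cls(members=members, pathology=pathology, go_bp=go_bp)


def _split_labels(value: object) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    text = str(value).strip()
    if not text or text == PLACEHOLDER:
        return []
    return [tok.strip() for tok in text.split(";") if tok.strip()]


@dataclass
class ModuleAssignment:
    per_gene: dict[str, list[str]]  # rat gene -> module ids (possibly empty)

    @property
    def in_any_module(self) -> set[str]:
        return {g for g, mods in self.per_gene.items() if mods}

    @property
    def n_in_any_module(self) -> int:
        return len(self.in_any_module)


def assign_modules(rat_genes: Iterable[str], context: ModuleContext) -> ModuleAssignment:
    """Module list per rat gene; genes outside all modules get []."""
    per_gene = {
        gene: sorted(mod for mod, members in context.members.items() if gene in members)
        for gene in sorted(set(rat_genes))
    }
    return ModuleAssignment(per_gene=per_gene)


def pathology_report(assignment: ModuleAssignment, context: ModuleContext) -> pd.DataFrame:
    """Rows (module, gene, pathology, go_bp) for pathology-linked modules.

    Only modules with at least one pathology label appear; an empty GO-BP
    list renders as the placeholder token.
    """
    rows = []
    for gene, modules in assignment.per_gene.items():
        for mod in modules:
            labels = context.pathology.get(mod, [])
            if not labels:
                continue
            go = context.go_bp.get(mod, [])
            rows.append(
                {
                    "module": mod,
                    "rat_gene": gene,
                    "pathology": "; ".join(labels),
                    "go_bp": "; ".join(go) if go else PLACEHOLDER,
                }
            )
    return pd.DataFrame(rows, columns=["module", "rat_gene", "pathology", "go_bp"]).sort_values(
        ["module", "rat_gene"], ignore_index=True
    )


def pathology_gene_set(
    ortholog_mapping: OrthologMapping,
    assignment: ModuleAssignment,
    context: ModuleContext,
) -> Mapping[int, bool]:
    """Per human gene: does any ortholog sit in a pathology-linked module?"""
    pathological_modules = {m for m, labels in context.pathology.items() if labels}
    flags = {}
    for human, rats in ortholog_mapping.per_gene.items():
        flags[human] = any(
            set(assignment.per_gene.get(rat, [])) & pathological_modules for rat in rats
        )
    return flags
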