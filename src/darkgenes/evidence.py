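"""Evidence integration: binary flags, sum score, tiers, exclusivity.

Each dark gene gets one boolean per evidence source (interactome presence
per snapshot, disease/literature counts, regulon and signature membership,
rat ortholog and module membership). The evidence score S is the plain sum
of flags; tiers follow fixed thresholds (high: S ≥ 8, moderate: S ≥ 4,
low: S ≥ 1, none: S = 0). Group-exclusivity flags mark genes perturbed
only by the most-DILI compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation import DarknessCall, dark_set
from .regulon_pathway import CompoundMapping
from .xspecies import ModuleAssignment, OrthologMapping

DEFAULT_SOURCES = (
    "PIN_BIANA",
    "PIN_HIPPIE",
    "PIN_INBIOMAP",
    "PIN_INTACT",
    "DISEASE_CURATED",
    "DISEASE_ALL",
    "GENERIF",
    "PUBTATOR",
    "REGULON",
    "SIGNATURE",
    "RAT_ORTHOLOG",
    "WGCNA_MODULE",
)

#: degree-table column → evidence source name
PIN_SOURCE_MAP = {
    "BIANA": "PIN_BIANA",
    "HIPPIE": "PIN_HIPPIE",
    "INBIOMAP": "PIN_INBIOMAP",
    "INTACT": "PIN_INTACT",
}


@dataclass
class TierParams:
    high_threshold: int = 8
    moderate_threshold: int = 4

    def tier_of(self, score: int) -> str:
        if score >= self.high_threshold:
            return "high"
        if score >= self.moderate_threshold:
            return "moderate"
        if score >= 1:
            return "low"
        return "none"


def build_evidence_matrix(
    darkness_calls: Sequence[DarknessCall],
    degree_table: pd.DataFrame,
    literature_counts: pd.DataFrame,
    regulon_mappings: Sequence[CompoundMapping],
    signature_mappings: Sequence[CompoundMapping],
    ortholog_mapping: OrthologMapping,
    module_assignment: ModuleAssignment,
    *,
    pin_source_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Gene × source boolean matrix over the dark-gene set.

    All inputs must be computed over the same dark genes; a mismatch
    between the darkness calls and the degree/literature tables raises
    with the symmetric difference. Absent evidence is False.
    """
    genes = sorted(dark_set(darkness_calls))
    pin_map = dict(pin_source_map or PIN_SOURCE_MAP)
    for name, frame in (("degree_table", degree_table), ("literature_counts", literature_counts)):
        diff = set(frame.index) ^ set(genes)
        if diff:
            raise ValueError(f"{name} gene set mismatch; symmetric difference: {sorted(diff)[:10]}")

    matrix = pd.DataFrame(False, index=pd.Index(genes, name="gene"), columns=list(DEFAULT_SOURCES))
    for snap_col, source in pin_map.items():
        if snap_col in degree_table.columns:
            matrix[source] = (degree_table[snap_col].fillna(0) >= 1).to_numpy()
    matrix["DISEASE_CURATED"] = (literature_counts["n_diseases_curated"] >= 1).to_numpy()
    matrix["DISEASE_ALL"] = (literature_counts["n_diseases_all"] >= 1).to_numpy()
    matrix["GENERIF"] = (literature_counts["n_generifs"] >= 1).to_numpy()
    matrix["PUBTATOR"] = (literature_counts["n_publications"] >= 1).to_numpy()

    regulon_hit = set().union(*(m.mapped_genes for m in regulon_mappings)) if regulon_mappings else set()
    signature_hit = set().union(*(m.mapped_genes for m in signature_mappings)) if signature_mappings else set()
    matrix["REGULON"] = [g in regulon_hit for g in genes]
    matrix["SIGNATURE"] = [g in signature_hit for g in genes]
    matrix["RAT_ORTHOLOG"] = [g in ortholog_mapping.per_gene for g in genes]
    in_module = ortholog_mapping.per_gene
    module_genes = module_assignment.in_any_module
    matrix["WGCNA_MODULE"] = [
        any(rat in module_genes for rat in in_module.get(g, [])) for g in genes
    ]
    return matrix


def score_and_tier(matrix: pd.DataFrame, params: TierParams | None = None) -> pd.DataFrame:
    """Evidence summary: score S (row sum of flags) and tier per gene."""
    params = params or TierParams()
    score = matrix.sum(axis=1).astype(int)
    return pd.DataFrame(
        {"score": score, "tier": [params.tier_of(s) for s in score]},
        index=matrix.index,
    )


def exclusivity_flags(
    deg_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    genes: Sequence[int],
    *,
    dili_group: str = "most_dili",
    no_dili_group: str = "no_dili",
    min_dili_compounds: int = 4,
) -> pd.DataFrame:
    """Group-exclusivity flags per gene.

    ``most_dili_exclusive``: DEG in ≥1 most-DILI compound and in no no-DILI
    compound. ``deg_in_4of5_dili``: DEG in ≥``min_dili_compounds`` most-DILI
    compounds and in no no-DILI compound (implies the first flag).
    """
    missing = [c for c in groups if c not in deg_tables]
    if missing:
        raise ValueError(f"missing DEG tables for compounds: {missing}")
    dili = [c for c, g in groups.items() if g == dili_group]
    nodili = [c for c, g in groups.items() if g == no_dili_group]
    rows = []
    for gene in genes:
        n_dili = sum(
            1 for c in dili if gene in deg_tables[c].index and bool(deg_tables[c].loc[gene, "is_deg"])
        )
        n_nodili = sum(
            1 for c in nodili if gene in deg_tables[c].index and bool(deg_tables[c].loc[gene, "is_deg"])
        )
        rows.append(
            {
                "gene": gene,
                "n_dili_deg": n_dili,
                "n_nodili_deg": n_nodili,
                "most_dili_exclusive": n_dili >= 1 and n_nodili == 0,
                "deg_in_4of5_dili": n_dili >= min_dili_compounds and n_nodili == 0,
            }
        )
    columns = ["gene", "n_dili_deg", "n_nodili_deg", "most_dili_exclusive", "deg_in_4of5_dili"]
    return pd.DataFrame(rows, columns=columns).set_index("gene")


def coverage_fraction(matrix: pd.DataFrame) -> tuple[float, int]:
    """(raw fraction with ≥1 evidence flag, floor-percent display)."""
    if matrix.empty:
        raise ValueError("empty evidence matrix")
    frac = float((matrix.sum(axis=1) >= 1).mean())
    return frac, int(frac * 100)
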