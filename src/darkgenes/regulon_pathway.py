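"""Mapping dark genes to TF regulons and pathway signatures.

A transcription-factor *regulon* is the target set of one TF; a pathway
*signature* is the gene set whose expression footprints one signaling
pathway's activity. For each compound, a regulator (TF or pathway) is
*mapped* when its gene set intersects that compound's dark genes —
membership, not an over-representation test (an optional hypergeometric
mode exists for exploratory use). Group-wise consensus intersects the
per-compound regulator sets, either strictly (an empty compound set forces
an empty consensus) or excluding empty compound sets, mirroring how a
compound with no mapped pathway is conventionally left out of a Venn
diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EMPTY_POLICIES = ("strict", "exclude_empty")


def load_regulon_table(
    path: str | Path,
    *,
    grades: set[str] | None = None,
    columns: Mapping[str, str] | None = None,
) -> dict[str, set[int]]:
    """Regulon TSV (tf, target, optional grade) → TF → target set.

    ``grades`` optionally restricts to given confidence grades.
    """
    cols = {"tf": "tf", "target": "target", "grade": "grade"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if grades is not None and cols["grade"] in df.columns:
        df = df[df[cols["grade"]].isin(grades)]
    table: dict[str, set[int]] = {}
    for tf, sub in df.groupby(cols["tf"]):
        targets = {int(t) for t in sub[cols["target"]]}
        if targets:
            table[str(tf)] = targets
    return table


def load_signature_table(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
) -> dict[str, set[int]]:
    """Signature TSV (pathway, gene) → pathway → signature gene set."""
    cols = {"pathway": "pathway", "gene": "gene"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(pw): {int(g) for g in sub[cols["gene"]]}
        for pw, sub in df.groupby(cols["pathway"])
        if len(sub)
    }


@dataclass
class CompoundMapping:
    """Regulators hit by one compound's dark genes."""

    compound: str
    regulator_set: set[str]
    mapped_genes: set[int]

    def __post_init__(self) -> None:
        if bool(self.regulator_set) != bool(self.mapped_genes):
            raise ValueError("regulator_set empty iff mapped_genes empty")


def map_regulators(
    dark_genes_by_compound: Mapping[str, set[int]],
    table: Mapping[str, set[int]],
    *,
    mode: str = "membership",
    background: set[int] | None = None,
    alpha: float = 0.05,
) -> list[CompoundMapping]:
    """Per-compound regulator mapping.

    ``membership`` (default): a regulator maps when its gene set intersects
    the compound's dark genes. ``hypergeometric``: additionally requires an
    over-representation p-value below ``alpha`` against ``background``
    (defaults to the union of all dark genes).
    """
    if mode not in ("membership", "hypergeometric"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "hypergeometric" and background is None:
        background = set().union(*dark_genes_by_compound.values()) if dark_genes_by_compound else set()
    mappings = []
    for compound in sorted(dark_genes_by_compound):
        dark = dark_genes_by_compound[compound]
        regulators: set[str] = set()
        covered: set[int] = set()
        for name, targets in table.items():
            hits = targets & dark
            if not hits:
                continue
            if mode == "hypergeometric":
                m = len(targets & background)  # type: ignore[arg-type]
                p = stats.hypergeom.sf(len(hits) - 1, len(background), m, len(dark & background))  # type: ignore[arg-type]
                if p >= alpha:
                    continue
            regulators.add(name)
            covered |= hits
        mappings.append(CompoundMapping(compound=compound, regulator_set=regulators, mapped_genes=covered))
    return mappings


@dataclass
class ConsensusResult:
    group: str
    per_compound: dict[str, set[str]]
    consensus: set[str]
    empty_policy: str
    venn_region_counts: dict[frozenset[str], int] = field(default_factory=dict)


def consensus_sets(
    mappings: Sequence[CompoundMapping],
    empty_policy: str = "strict",
    group: str = "",
) -> ConsensusResult:
    """Intersect per-compound regulator sets under an empty-set policy."""
    if len(mappings) < 2:
        raise ValueError("consensus needs at least two compound mappings")
    if empty_policy not in EMPTY_POLICIES:
        raise ValueError(f"empty_policy must be one of {EMPTY_POLICIES}")
    per_compound = {m.compound: set(m.regulator_set) for m in mappings}
    sets = list(per_compound.values())
    if empty_policy == "exclude_empty":
        sets = [s for s in sets if s]
    if not sets:
        logger.warning("all regulator sets empty for group %r", group)
        consensus: set[str] = set()
    else:
        consensus = set.intersection(*sets)
    return ConsensusResult(
        group=group,
        per_compound=per_compound,
        consensus=consensus,
        empty_policy=empty_policy,
        venn_region_counts=venn_region_counts(list(per_compound.values()), list(per_compound)),
    )


def venn_region_counts(sets: Sequence[set], labels: Sequence[str]) -> dict[frozenset[str], int]:
    """Disjoint Venn region sizes over 2–6 sets.

    Keys are frozensets of the labels whose region the count belongs to;
    only non-empty regions appear. Region masses sum to the union size and
    the all-labels region equals the strict intersection.
    """
    if not 2 <= len(sets) <= 6:
        raise ValueError("venn regions are defined for 2 to 6 sets")
    if len(labels) != len(sets):
        raise ValueError("labels must match sets")
    by_label = dict(zip(labels, sets))
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(by_label[l] for l in combo))
            outside = set().union(*(by_label[l] for l in labels if l not in combo)) if r < len(labels) else set()
            count = len(inside - outside)
            if count:
                regions[frozenset(combo)] = count
    return regions


def mapping_overview(
    dark_genes_by_compound: Mapping[str, set[int]],
    regulon_mappings: Sequence[CompoundMapping],
    signature_mappings: Sequence[CompoundMapping],
) -> pd.DataFrame:
    """Per-compound overview: dark genes, mapped genes and regulator counts."""
    reg = {m.compound: m for m in regulon_mappings}
    sig = {m.compound: m for m in signature_mappings}
    rows = []
    for compound in sorted(dark_genes_by_compound):
        rows.append(
            {
                "compound": compound,
                "n_dark_genes": len(dark_genes_by_compound[compound]),
                "n_dark_in_regulons": len(reg[compound].mapped_genes) if compound in reg else 0,
                "n_mapped_tfs": len(reg[compound].regulator_set) if compound in reg else 0,
                "n_dark_in_signatures": len(sig[compound].mapped_genes) if compound in sig else 0,
                "n_mapped_pathways": len(sig[compound].regulator_set) if compound in sig else 0,
            }
        )
    return pd.DataFrame(rows).set_index("compound")
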