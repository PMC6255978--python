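"""Annotation universe construction and dark-gene classification.

A gene is *dark* when it is absent from every configured annotation
resource. The default universe has five resources with these filters:

- ``GO_BP``: only rows of the biological-process aspect (code P);
- ``Reactome`` / ``MSigDB``: gene-set (GMT) membership, unfiltered;
- ``PathwayCommons``: interactions without a pathway annotation are
  discarded before collecting participants;
- ``OmniPath``: interactions supported only by pure protein–protein
  interaction databases (BioGRID, HPRD, IntAct) are discarded.

Darkness of DEGs is always contrasted with the same classification run on
the full measured background (the array's gene list).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .idmap import BIOTYPES, GeneCatalog, map_to_entrez

logger = logging.getLogger(__name__)

PPI_ONLY_SOURCES = frozenset({"BioGRID", "HPRD", "IntAct"})


@dataclass
class GeneSetResource:
    """One named annotation resource: the set of annotated Entrez IDs."""

    name: str
    annotated_genes: set[int]
    provenance: str = ""


@dataclass
class AnnotationUniverse:
    resources: list[GeneSetResource] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.resources]
        if len(names) != len(set(names)):
            raise ValueError("resource names must be unique")

    @property
    def union_annotated(self) -> set[int]:
        out: set[int] = set()
        for res in self.resources:
            out |= res.annotated_genes
        return out

    def resource_names(self) -> list[str]:
        return [r.name for r in self.resources]


@dataclass(frozen=True)
class DarknessCall:
    gene: int
    dark: bool
    present_in: frozenset[str]

    def __post_init__(self) -> None:
        if self.dark != (not self.present_in):
            raise ValueError("dark must hold exactly when present_in is empty")


@dataclass
class CoverageReport:
    """Dark fraction with both display-rounding conventions.

    ``percent_rounded`` rounds half-up to the nearest integer;
    ``percent_floor`` truncates. Both are carried because published
    summaries mix the two conventions.
    """

    n_input: int
    n_dark: int

    def __post_init__(self) -> None:
        if self.n_input <= 0:
            raise ValueError("coverage report needs a non-empty input set")
        if not 0 <= self.n_dark <= self.n_input:
            raise ValueError("n_dark must lie in [0, n_input]")

    @property
    def dark_fraction(self) -> float:
        return 100.0 * self.n_dark / self.n_input

    @property
    def percent_rounded(self) -> int:
        return int(math.floor(self.dark_fraction + 0.5))

    @property
    def percent_floor(self) -> int:
        return int(math.floor(self.dark_fraction))


def parse_gmt(path: str | Path, catalog: GeneCatalog, name: str = "MSigDB") -> GeneSetResource:
    """GMT gene-set file → resource; members resolved through the catalog."""
    members: list[str] = []
    n_sets = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    logger.warning("%s line %d has <3 fields; skipped", path, lineno)
                continue
            n_sets += 1
            members.extend(tok for tok in fields[2:] if tok.strip())
    mapping = map_to_entrez(members, catalog)
    if mapping.unmapped or mapping.ambiguous:
        logger.warning(
            "%s: %d unmapped, %d ambiguous member tokens",
            path, len(mapping.unmapped), len(mapping.ambiguous),
        )
    return GeneSetResource(
        name=name,
        annotated_genes=mapping.mapped_ids(),
        provenance=f"{path} ({n_sets} sets)",
    )


def parse_go_annotations(
    path: str | Path,
    catalog: GeneCatalog,
    aspect_filter: str = "P",
    *,
    columns: Mapping[str, str] | None = None,
) -> GeneSetResource:
    """GAF-like TSV → GO_BP resource (only the requested aspect counts)."""
    cols = {"gene": "gene", "term": "go_term", "aspect": "aspect"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    known_aspects = {"P", "F", "C"}
    bad = ~df[cols["aspect"]].isin(known_aspects)
    if bad.any():
        logger.warning("%s: %d rows with unknown aspect code skipped", path, int(bad.sum()))
    kept = df[df[cols["aspect"]] == aspect_filter]
    mapping = map_to_entrez(kept[cols["gene"]].tolist(), catalog)
    return GeneSetResource(
        name="GO_BP" if aspect_filter == "P" else f"GO_{aspect_filter}",
        annotated_genes=mapping.mapped_ids(),
        provenance=f"{path} (aspect {aspect_filter})",
    )


def parse_pathway_commons(
    path: str | Path,
    catalog: GeneCatalog,
    *,
    columns: Mapping[str, str] | None = None,
) -> GeneSetResource:
    """Interaction TSV → resource keeping only pathway-annotated rows.

    A row contributes its participants only when its pathway field is
    non-empty after whitespace stripping.
    """
    cols = {"a": "participant_a", "b": "participant_b", "pathway": "pathway"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    tokens: list[str] = []
    for _, row in df.iterrows():
        a, b = row.get(cols["a"]), row.get(cols["b"])
        if pd.isna(a) or pd.isna(b) or not str(a).strip() or not str(b).strip():
            logger.warning("row missing participants skipped: %r", dict(row))
            continue
        pathway = row.get(cols["pathway"])
        if pd.isna(pathway) or not str(pathway).strip():
            continue
        tokens.extend([str(a), str(b)])
    mapping = map_to_entrez(tokens, catalog)
    return GeneSetResource("PathwayCommons", mapping.mapped_ids(), provenance=str(path))


def parse_omnipath(
    path: str | Path,
    catalog: GeneCatalog,
    ppi_only_sources: frozenset[str] = PPI_ONLY_SOURCES,
    *,
    columns: Mapping[str, str] | None = None,
) -> GeneSetResource:
    """Interaction TSV → resource dropping PPI-only-supported rows.

    A row whose source-database set is a (non-empty or empty) subset of
    ``ppi_only_sources`` is dropped; an empty source list counts as
    PPI-only and is dropped with a warning.
    """
    cols = {"a": "source", "b": "target", "sources": "sources"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    tokens: list[str] = []
    for _, row in df.iterrows():
        raw = row.get(cols["sources"])
        srcs = {s.strip() for s in str(raw).split(";") if s.strip()} if not pd.isna(raw) else set()
        if not srcs:
            logger.warning("interaction with empty source list treated as PPI-only: %r", dict(row))
            continue
        if srcs <= ppi_only_sources:
            continue
        tokens.extend([str(row[cols["a"]]), str(row[cols["b"]])])
    mapping = map_to_entrez(tokens, catalog)
    return GeneSetResource("OmniPath", mapping.mapped_ids(), provenance=str(path))


def classify_darkness(genes: Iterable[int], universe: AnnotationUniverse) -> list[DarknessCall]:
    """Dark ⇔ absent from every resource of the universe."""
    if not universe.resources:
        raise ValueError("universe must hold at least one resource")
    calls = []
    for gene in sorted(set(genes)):
        present = frozenset(r.name for r in universe.resources if gene in r.annotated_genes)
        calls.append(DarknessCall(gene=gene, dark=not present, present_in=present))
    return calls


def dark_set(calls: Iterable[DarknessCall]) -> set[int]:
    return {c.gene for c in calls if c.dark}


def coverage_report(
    calls: Sequence[DarknessCall],
    background_calls: Sequence[DarknessCall],
) -> tuple[CoverageReport, CoverageReport]:
    """Coverage for the input gene set and the array background."""
    if not calls or not background_calls:
        raise ValueError("coverage_report needs non-empty call lists")
    fg = CoverageReport(n_input=len(calls), n_dark=len(dark_set(calls)))
    bg = CoverageReport(n_input=len(background_calls), n_dark=len(dark_set(background_calls)))
    return fg, bg


def tally_biotypes(
    dark_calls: Sequence[DarknessCall],
    catalog: GeneCatalog,
    group_membership: Mapping[str, set[int]] | None = None,
) -> pd.DataFrame:
    """Biotype × column count table over dark genes.

    Columns are the groups in ``group_membership`` plus ``all`` (every dark
    gene in ``dark_calls``). Genes of biotype ``unknown`` are reported on a
    separate ``uncategorized`` row and excluded from the categorized total.
    A gene dark in several groups counts once per group column.
    """
    dark = sorted(dark_set(dark_calls))
    groups = dict(group_membership or {})
    columns = list(groups) + ["all"]
    cats = [b for b in BIOTYPES if b != "unknown"]
    table = pd.DataFrame(0, index=cats + ["total", "uncategorized"], columns=columns)
    for col in columns:
        members = dark if col == "all" else [g for g in dark if g in groups[col]]
        for gene in members:
            bt = catalog.biotype_of(gene)
            if bt == "unknown":
                table.loc["uncategorized", col] += 1
            else:
                table.loc[bt, col] += 1
        table.loc["total", col] = int(table.loc[cats, col].sum())
    return table
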