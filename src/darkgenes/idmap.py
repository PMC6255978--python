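"""Gene identifier harmonization.

All downstream stages key genes by Entrez ID. Input files (gene-set
collections, interaction tables, literature tables) mix primary symbols,
synonyms and UniProt accessions; this module loads a frozen gene catalog
(NCBI ``gene_info``-style plus an optional HGNC-style UniProt correspondence
and an Ensembl-style biotype table) and resolves arbitrary tokens through a
fixed cascade:

0. a numeric token that is a catalog Entrez ID maps to itself;
1. primary-symbol match;
2. synonym match;
3. UniProt accession match.

A token with two or more surviving candidates at its winning step is
reported as ambiguous, never silently resolved — a mis-mapped gene would
corrupt darkness calls downstream. Matching is case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed biotype vocabulary (Ensembl-style); anything else collapses to
#: ``unknown`` and pseudogene subtypes collapse to ``pseudogene``.
BIOTYPES = (
    "protein_coding",
    "antisense",
    "lincRNA",
    "processed_transcript",
    "pseudogene",
    "snoRNA",
    "sense_intronic",
    "sense_overlapping",
    "miRNA",
    "TEC",
    "unknown",
)


def normalize_biotype(raw: str | None) -> str:
    """Map a raw biotype label onto the closed vocabulary."""
    if raw is None:
        return "unknown"
    label = str(raw).strip()
    if not label or label.lower() in ("nan", "none", "-"):
        return "unknown"
    if "pseudogene" in label.lower():
        return "pseudogene"
    for known in BIOTYPES:
        if label.lower() == known.lower():
            return known
    return "unknown"


@dataclass(frozen=True)
class GeneRecord:
    """One gene: Entrez identity, naming and biotype."""

    entrez_id: int
    symbol: str
    synonyms: frozenset[str] = frozenset()
    uniprot_ids: frozenset[str] = frozenset()
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.entrez_id <= 0:
            raise ValueError(f"entrez_id must be positive, got {self.entrez_id}")
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


class GeneCatalog:
    """Frozen snapshot of gene records with symbol and UniProt indices.

    Indices are rebuilt deterministically from the records; keys are
    lower-cased for case-insensitive lookup.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: dict[int, GeneRecord] = {}
        for rec in records:
            if rec.entrez_id in self.records:
                logger.warning("duplicate Entrez ID %d: keeping first record", rec.entrez_id)
                continue
            self.records[rec.entrez_id] = rec
        self.symbol_index: dict[str, set[int]] = {}
        self.synonym_index: dict[str, set[int]] = {}
        self.uniprot_index: dict[str, set[int]] = {}
        for rec in self.records.values():
            self.symbol_index.setdefault(rec.symbol.lower(), set()).add(rec.entrez_id)
            for syn in rec.synonyms:
                self.synonym_index.setdefault(syn.lower(), set()).add(rec.entrez_id)
            for acc in rec.uniprot_ids:
                self.uniprot_index.setdefault(acc.lower(), set()).add(rec.entrez_id)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, entrez_id: int) -> bool:
        return entrez_id in self.records

    def __getitem__(self, entrez_id: int) -> GeneRecord:
        return self.records[entrez_id]

    @property
    def entrez_ids(self) -> set[int]:
        return set(self.records)

    def biotype_of(self, entrez_id: int) -> str:
        rec = self.records.get(entrez_id)
        return rec.biotype if rec is not None else "unknown"


@dataclass
class MappingResult:
    """Partition of input tokens into mapped / unmapped / ambiguous."""

    mapped: dict[str, int] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return len(self.mapped) + len(self.unmapped) + len(self.ambiguous)

    def mapped_ids(self) -> set[int]:
        return set(self.mapped.values())


def _split_multi(value: object, seps: str = "|,") -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    text = str(value).strip()
    if not text or text == "-":
        return frozenset()
    for sep in seps[1:]:
        text = text.replace(sep, seps[0])
    return frozenset(tok.strip() for tok in text.split(seps[0]) if tok.strip() and tok.strip() != "-")


def load_gene_catalog(
    gene_info_table: str | Path | pd.DataFrame,
    biotype_table: str | Path | pd.DataFrame | None = None,
    hgnc_table: str | Path | pd.DataFrame | None = None,
    *,
    columns: Mapping[str, str] | None = None,
) -> GeneCatalog:
    """Build a :class:`GeneCatalog` from a gene_info-style TSV.

    Parameters
    ----------
    gene_info_table
        TSV (or DataFrame) with columns for Entrez ID, symbol and
        pipe/comma-delimited synonyms. Default column names follow NCBI
        gene_info (``GeneID``, ``Symbol``, ``Synonyms``); override via
        ``columns`` with keys ``entrez``, ``symbol``, ``synonyms``.
    biotype_table
        Optional TSV/DataFrame with columns ``entrez`` (or ``GeneID``) and
        ``biotype``; genes missing from it get biotype ``unknown``.
    hgnc_table
        Optional HGNC-style TSV/DataFrame carrying the UniProt↔Entrez
        correspondence (columns ``entrez_id`` and ``uniprot_ids``).

    Malformed rows are skipped with a logged warning; duplicate Entrez IDs
    keep the first occurrence.
    """
    cols = {"entrez": "GeneID", "symbol": "Symbol", "synonyms": "Synonyms"}
    if columns:
        cols.update(columns)
    df = _as_frame(gene_info_table)

    biotypes: dict[int, str] = {}
    if biotype_table is not None:
        bt = _as_frame(biotype_table)
        ent_col = "entrez" if "entrez" in bt.columns else "GeneID"
        for _, row in bt.iterrows():
            try:
                biotypes[int(row[ent_col])] = normalize_biotype(row["biotype"])
            except (ValueError, TypeError, KeyError):
                logger.warning("skipping malformed biotype row: %r", dict(row))

    uniprot: dict[int, set[str]] = {}
    if hgnc_table is not None:
        hg = _as_frame(hgnc_table)
        for _, row in hg.iterrows():
            try:
                eid = int(row["entrez_id"])
            except (ValueError, TypeError):
                logger.warning("skipping HGNC row without Entrez ID: %r", dict(row))
                continue
            uniprot.setdefault(eid, set()).update(_split_multi(row.get("uniprot_ids")))

    records = []
    for _, row in df.iterrows():
        try:
            eid = int(row[cols["entrez"]])
            symbol = str(row[cols["symbol"]]).strip()
            if eid <= 0 or not symbol or symbol.lower() == "nan":
                raise ValueError
        except (ValueError, TypeError, KeyError):
            logger.warning("skipping malformed gene_info row: %r", dict(row))
            continue
        records.append(
            GeneRecord(
                entrez_id=eid,
                symbol=symbol,
                synonyms=_split_multi(row.get(cols["synonyms"])),
                uniprot_ids=frozenset(uniprot.get(eid, ())),
                biotype=biotypes.get(eid, "unknown"),
            )
        )
    return GeneCatalog(records)


def map_to_entrez(tokens: Iterable[str], catalog: GeneCatalog) -> MappingResult:
    """Resolve tokens to Entrez IDs through the fixed cascade.

    Distinct tokens are partitioned into mapped / unmapped / ambiguous;
    duplicated input tokens are resolved once.
    """
    result = MappingResult()
    seen: set[str] = set()
    for token in tokens:
        token = str(token).strip() if token is not None else ""
        if token in seen:
            continue
        seen.add(token)
        if not token:
            result.unmapped.append(token)
            continue
        candidates = _cascade(token, catalog)
        if candidates is None:
            result.unmapped.append(token)
        elif len(candidates) == 1:
            result.mapped[token] = next(iter(candidates))
        else:
            result.ambiguous.append(token)
    return result


def _cascade(token: str, catalog: GeneCatalog) -> set[int] | None:
    key = token.lower()
    if token.isdigit() and int(token) in catalog:
        return {int(token)}
    for index in (catalog.symbol_index, catalog.synonym_index, catalog.uniprot_index):
        hit = index.get(key)
        if hit:
            return set(hit)
    return None


def _as_frame(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table, sep="\t", dtype=str, comment="#")
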