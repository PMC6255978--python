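"""Literature-derived evidence counts per gene.

Three snapshot tables feed this module: gene–disease associations (with a
curated/all source tier), GeneRIF entries, and text-mined gene–publication
links. Counting is over distinct disease IDs / RIF rows / PMIDs; no text
mining or disease-ontology mapping happens here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

TIERS = ("curated", "all")


def _as_frame(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.read_csv(table, sep="\t", dtype=str)


def count_disease_associations(
    assoc_table: str | Path | pd.DataFrame,
    tier: str = "all",
    *,
    columns: Mapping[str, str] | None = None,
) -> pd.Series:
    """Distinct disease IDs per gene within a source tier.

    ``tier='curated'`` keeps only curated-source rows; ``tier='all'`` keeps
    everything (curated rows are a subset of all).
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}, got {tier!r}")
    cols = {"gene": "gene", "disease": "disease_id", "tier": "source_tier"}
    if columns:
        cols.update(columns)
    df = _as_frame(assoc_table)
    if tier == "curated":
        df = df[df[cols["tier"]] == "curated"]
    counts = df.groupby(df[cols["gene"]].astype(int))[cols["disease"]].nunique()
    return counts.rename(f"n_diseases_{tier}").sort_index()


def count_generifs(
    rif_table: str | Path | pd.DataFrame,
    highlight_threshold: int = 10,
    *,
    columns: Mapping[str, str] | None = None,
) -> tuple[pd.Series, set[int]]:
    """Per-gene GeneRIF row counts and the highly-described highlight set.

    The highlight set holds genes with at least ``highlight_threshold``
    RIF entries (default 10).
    """
    cols = {"gene": "gene"}
    if columns:
        cols.update(columns)
    df = _as_frame(rif_table)
    if df.empty:
        return pd.Series(dtype=int, name="n_generifs"), set()
    counts = df.groupby(df[cols["gene"]].astype(int)).size().rename("n_generifs").sort_index()
    highlight = set(counts.index[counts >= highlight_threshold])
    return counts, highlight


def count_publications(
    gene2pub_table: str | Path | pd.DataFrame,
    *,
    columns: Mapping[str, str] | None = None,
) -> pd.Series:
    """Distinct publication IDs per gene.

    A publication mentioning several genes increments each of them; the
    same PMID repeated for one gene counts once.
    """
    cols = {"gene": "gene", "pmid": "pmid"}
    if columns:
        cols.update(columns)
    df = _as_frame(gene2pub_table)
    if df.empty:
        return pd.Series(dtype=int, name="n_publications")
    counts = df.groupby(df[cols["gene"]].astype(int))[cols["pmid"]].nunique()
    return counts.rename("n_publications").sort_index()


def evidence_count_table(
    disease_table: str | Path | pd.DataFrame,
    rif_table: str | Path | pd.DataFrame,
    gene2pub_table: str | Path | pd.DataFrame,
    genes: set[int] | None = None,
) -> pd.DataFrame:
    """Join the three counters into one gene × counter table.

    Restricted to ``genes`` when given; absent genes get zero counts.
    """
    curated = count_disease_associations(disease_table, "curated")
    alltier = count_disease_associations(disease_table, "all")
    rifs, _ = count_generifs(rif_table)
    pubs = count_publications(gene2pub_table)
    table = pd.concat(
        {
            "n_diseases_curated": curated,
            "n_diseases_all": alltier,
            "n_generifs": rifs,
            "n_publications": pubs,
        },
        axis=1,
    )
    if genes is not None:
        table = table.reindex(sorted(genes))
    table.index.name = "gene"
    return table.fillna(0).astype(int)
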