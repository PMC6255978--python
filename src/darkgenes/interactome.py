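"""Dark-gene connectivity across protein-interaction-network snapshots.

Each snapshot is a cleaned undirected edge set from one interaction
database release: self-loops removed, duplicate and reversed pairs
collapsed, optionally predicted interactions and low-confidence edges
dropped. A gene is *present* in a snapshot only when it retains at least
one edge after cleaning, so presence ⇔ degree ≥ 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .idmap import GeneCatalog, map_to_entrez

logger = logging.getLogger(__name__)


@dataclass
class InteractomeSnapshot:
    """Named undirected interaction network over Entrez IDs."""

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def node_set(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: int) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0


def load_edge_list(
    path: str | Path,
    catalog: GeneCatalog,
    name: str,
    *,
    columns: Mapping[str, str] | None = None,
    drop_predicted: bool = False,
    min_score: float | None = None,
) -> InteractomeSnapshot:
    """Read a two-column interaction TSV into a cleaned snapshot.

    Column roles default to ``gene_a`` / ``gene_b`` with optional
    ``predicted`` (truthy flag) and ``score`` columns; override via
    ``columns``. Unmappable participants drop the row (logged); direction
    is ignored; self-loops and duplicates are removed.
    """
    cols = {"a": "gene_a", "b": "gene_b", "predicted": "predicted", "score": "score"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    graph = nx.Graph()
    n_dropped = 0
    tokens = pd.unique(pd.concat([df[cols["a"]], df[cols["b"]]]).astype(str))
    mapping = map_to_entrez(tokens, catalog).mapped
    for _, row in df.iterrows():
        if drop_predicted and cols["predicted"] in df.columns:
            flag = str(row[cols["predicted"]]).strip().lower()
            if flag in ("1", "true", "yes", "y"):
                continue
        if min_score is not None and cols["score"] in df.columns:
            try:
                if float(row[cols["score"]]) < min_score:
                    continue
            except (TypeError, ValueError):
                pass
        a = mapping.get(str(row[cols["a"]]).strip())
        b = mapping.get(str(row[cols["b"]]).strip())
        if a is None or b is None:
            n_dropped += 1
            continue
        if a == b:
            continue
        graph.add_edge(a, b)
    if n_dropped:
        logger.warning("%s: dropped %d rows with unmappable participants", name, n_dropped)
    return InteractomeSnapshot(name=name, graph=graph)


def degree_profile(genes: Iterable[int], snapshots: Sequence[InteractomeSnapshot]) -> pd.DataFrame:
    """Gene × snapshot degree table.

    Entries are NaN for genes absent from a snapshot (no retained edge);
    the ``n_snapshots_present`` column counts non-absent entries per gene.
    """
    genes = sorted(set(genes))
    data = {}
    for snap in snapshots:
        # presence requires >=1 retained edge; isolated nodes count as absent
        data[snap.name] = [
            float(snap.degree(g)) if g in snap.graph and snap.degree(g) > 0 else float("nan")
            for g in genes
        ]
    table = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    table["n_snapshots_present"] = table.notna().sum(axis=1).astype(int)
    return table


def presence_summary(table: pd.DataFrame) -> tuple[int, int]:
    """(present in ≥1 snapshot, present in all snapshots) gene counts."""
    n_snapshots = table.shape[1] - 1  # last column is the presence count
    present = table["n_snapshots_present"]
    return int((present >= 1).sum()), int((present == n_snapshots).sum())


def per_snapshot_presence(table: pd.DataFrame) -> dict[str, int]:
    """Number of profiled genes present in each snapshot."""
    return {
        col: int(table[col].notna().sum())
        for col in table.columns
        if col != "n_snapshots_present"
    }


RANK_STATISTICS = ("max_degree", "sum_degree", "mean_degree")


def top_connected(table: pd.DataFrame, k: int = 10, rank_statistic: str = "max_degree") -> pd.DataFrame:
    """Top-k genes by a degree summary across snapshots.

    Ties break by ascending Entrez ID; genes absent everywhere rank last.
    Requesting more genes than profiled returns all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rank_statistic not in RANK_STATISTICS:
        raise ValueError(f"rank_statistic must be one of {RANK_STATISTICS}")
    degrees = table.drop(columns=["n_snapshots_present"])
    stat = {
        "max_degree": degrees.max(axis=1),
        "sum_degree": degrees.sum(axis=1),
        "mean_degree": degrees.mean(axis=1),
    }[rank_statistic].fillna(0.0)
    order = sorted(table.index, key=lambda g: (-stat.loc[g], g))
    out = table.loc[order[: min(k, len(order))]].copy()
    out["rank_statistic"] = stat.loc[out.index]
    return out


def degree_histogram(table: pd.DataFrame, snapshot: str, bin_edges: Sequence[float] | None = None) -> pd.Series:
    """Histogram of degrees on log-spaced bins (reporting aid)."""
    import numpy as np

    degrees = table[snapshot].dropna()
    if bin_edges is None:
        upper = max(float(degrees.max()) if len(degrees) else 1.0, 1.0)
        bin_edges = np.unique(np.ceil(np.logspace(0, np.log10(upper + 1), 12)))
    counts, edges = np.histogram(degrees, bins=bin_edges)
    labels = [f"[{int(lo)},{int(hi)})" for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.Series(counts, index=labels, name=snapshot)
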