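"""Per-compound differential expression from a log2 expression matrix.

The unit of analysis is one compound at its highest dose and latest time
point, compared against time-matched controls. A gene is a DEG when it
passes both gates: ``|log2FC| >= log2(1.5)`` (the exact value, not the
rounded 0.585) and Benjamini–Hochberg FDR below 0.05.

Three test statistics are offered. ``eb_moderated`` (default) shrinks each
gene's pooled variance toward the mean pooled variance with a fixed prior
degrees of freedom, which stabilizes the t statistic at the tiny replicate
numbers typical of toxicogenomics designs (n = 3 per arm); ``t_pooled`` and
``t_welch`` are the classical alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2_FC_15 = math.log2(1.5)

TEST_METHODS = ("eb_moderated", "t_pooled", "t_welch")


@dataclass
class DEGParams:
    """Gates and test choice for DEG calling."""

    fc_threshold: float = 1.5
    fdr_alpha: float = 0.05
    test_method: str = "eb_moderated"
    prior_df: float = 4.0  # eb_moderated only

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.test_method not in TEST_METHODS:
            raise ValueError(f"test_method must be one of {TEST_METHODS}")

    @property
    def log2_fc_threshold(self) -> float:
        return math.log2(self.fc_threshold)


class ExpressionMatrix:
    """Gene × sample log2 intensities with per-sample metadata.

    ``values`` is a DataFrame indexed by Entrez ID with sample columns;
    ``sample_meta`` is indexed by sample id with columns ``compound``,
    ``dose_level``, ``time_h``, ``role`` (treated/control) and optional
    ``group``. Controls carry the compound label of the treatment they are
    time-matched to.
    """

    def __init__(self, values: pd.DataFrame, sample_meta: pd.DataFrame):
        missing = set(values.columns) - set(sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if not set(sample_meta["role"]) <= {"treated", "control"}:
            raise ValueError("role must be 'treated' or 'control'")
        self.values = values
        self.sample_meta = sample_meta.loc[list(values.columns)]

    @classmethod
    def from_files(cls, values_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        values.index = values.index.astype(int)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def compounds(self) -> list[str]:
        treated = self.sample_meta[self.sample_meta["role"] == "treated"]
        return sorted(treated["compound"].unique())

    def arms(self, compound: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Treated and time-matched control sub-matrices for one compound."""
        meta = self.sample_meta
        trt = meta[(meta["compound"] == compound) & (meta["role"] == "treated")]
        ctl = meta[(meta["compound"] == compound) & (meta["role"] == "control")]
        if len(trt) == 0:
            raise ValueError(f"no treated samples for compound {compound!r}")
        if len(ctl) == 0:
            raise ValueError(f"no control samples for compound {compound!r}")
        return self.values[list(trt.index)], self.values[list(ctl.index)]

    def select_stratum(self, dose_level: str | None = None, time_h: float | None = None) -> "ExpressionMatrix":
        """Metadata filter, e.g. highest dose and latest time point."""
        meta = self.sample_meta
        keep = pd.Series(True, index=meta.index)
        if dose_level is not None:
            keep &= meta["dose_level"] == dose_level
        if time_h is not None:
            keep &= meta["time_h"] == time_h
        samples = list(meta.index[keep])
        return ExpressionMatrix(self.values[samples], meta.loc[samples])


def compute_log2fc(matrix: ExpressionMatrix, compound: str) -> pd.Series:
    """Mean(log2 treated) − mean(log2 control), per gene."""
    trt, ctl = matrix.arms(compound)
    return (trt.mean(axis=1) - ctl.mean(axis=1)).rename("log2fc")


def test_differential(
    matrix: ExpressionMatrix,
    compound: str,
    method: str = "eb_moderated",
    prior_df: float = 4.0,
) -> pd.Series:
    """Two-sided per-gene p-values for treated vs control.

    Genes with zero variance in both arms and equal means get p = 1 (the
    no-signal convention).
    """
    trt, ctl = matrix.arms(compound)
    if trt.shape[1] < 2 or ctl.shape[1] < 2:
        raise ValueError(f"need >=2 samples per arm for {compound!r}")
    x, y = trt.to_numpy(float), ctl.to_numpy(float)
    if method == "t_pooled":
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    elif method == "t_welch":
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    elif method == "eb_moderated":
        p = _moderated_t_pvalues(x, y, prior_df)
    else:
        raise ValueError(f"unknown test method {method!r}")
    p = np.asarray(p, float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p[degenerate & (x.mean(axis=1) == y.mean(axis=1))] = 1.0
    p[degenerate & (x.mean(axis=1) != y.mean(axis=1))] = 0.0
    return pd.Series(np.clip(p, 0.0, 1.0), index=matrix.genes, name="p_value")


def _moderated_t_pvalues(x: np.ndarray, y: np.ndarray, prior_df: float) -> np.ndarray:
    # Pooled per-gene variance shrunk toward the grand mean variance with
    # prior_df pseudo-observations; t referred to df + prior_df.
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df
    s2_prior = float(np.mean(s2))
    s2_post = (prior_df * s2_prior + df * s2) / (prior_df + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    t = np.where(np.isfinite(t), t, 0.0)
    return 2 * stats.t.sf(np.abs(t), df + prior_df)


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(list(p_values) if not isinstance(p_values, (np.ndarray, pd.Series)) else p_values, float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not adjustable")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(matrix: ExpressionMatrix, compound: str, params: DEGParams | None = None) -> pd.DataFrame:
    """DEG table for one compound: log2fc, p_value, fdr_q, is_deg."""
    params = params or DEGParams()
    log2fc = compute_log2fc(matrix, compound)
    p = test_differential(matrix, compound, params.test_method, params.prior_df)
    q = pd.Series(adjust_bh(p.to_numpy()), index=matrix.genes, name="fdr_q")
    is_deg = (log2fc.abs() >= params.log2_fc_threshold) & (q < params.fdr_alpha)
    return pd.DataFrame({"log2fc": log2fc, "p_value": p, "fdr_q": q, "is_deg": is_deg})


def deg_sets(deg_tables: Mapping[str, pd.DataFrame]) -> dict[str, set[int]]:
    """Per-compound DEG gene sets from DEG tables."""
    return {c: set(t.index[t["is_deg"]]) for c, t in deg_tables.items()}


@dataclass
class GroupUnion:
    per_group: dict[str, set[int]]
    overall: set[int]
    per_compound_counts: dict[str, int] = field(default_factory=dict)


def union_group_degs(
    deg_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
) -> GroupUnion:
    """Group-wise and overall DEG unions plus per-compound counts."""
    sets = deg_sets(deg_tables)
    missing = [c for c in sets if c not in groups]
    if missing:
        raise ValueError(f"compounds without group label: {missing}")
    per_group: dict[str, set[int]] = {}
    for compound, genes in sets.items():
        per_group.setdefault(groups[compound], set()).update(genes)
    overall = set().union(*per_group.values()) if per_group else set()
    return GroupUnion(
        per_group=per_group,
        overall=overall,
        per_compound_counts={c: len(g) for c, g in sets.items()},
    )
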