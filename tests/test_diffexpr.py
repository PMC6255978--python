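"""Differential expression: fold changes, tests, BH adjustment, DEG gates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from darkgenes.diffexpr import (
    DEGParams,
    ExpressionMatrix,
    adjust_bh,
    call_degs,
    compute_log2fc,
    union_group_degs,
)
from darkgenes.diffexpr import test_differential as run_diff_test


def bh_reference(p):
    """Quadratic-time Benjamini–Hochberg step-up: independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= pi]
        q[i] = min(1.0, min(candidates))
    return q


class TestLog2FC:
    def test_equivalent_fc_threshold(self, tiny_expression):
        # control mean 5.000, treated mean 5.585: exactly the 1.5-fold gate
        fc = compute_log2fc(tiny_expression, "A")
        assert fc.loc[101] == pytest.approx(0.585)
        assert abs(fc.loc[101]) >= math.log2(1.5) - 1e-9

    def test_identical_arms_zero(self, tiny_expression):
        fc = compute_log2fc(tiny_expression, "B")
        assert fc.loc[102] == 0.0

    def test_negative_two(self, tiny_expression):
        # treated mean 4.0, control mean 6.0
        assert compute_log2fc(tiny_expression, "A").loc[102] == pytest.approx(-2.0)

    def test_missing_controls_named_in_error(self, tiny_expression):
        meta = tiny_expression.sample_meta.copy()
        values = tiny_expression.values
        treated_only = meta[(meta["compound"] != "A") | (meta["role"] == "treated")]
        m = ExpressionMatrix(values[list(treated_only.index)], treated_only)
        with pytest.raises(ValueError, match="A"):
            compute_log2fc(m, "A")


class TestDifferentialTest:
    def test_constant_arms_give_p_one(self, tiny_expression):
        # gene 102 of compound B: both arms constant and equal
        p = run_diff_test(tiny_expression, "B", method="t_pooled")
        assert p.loc[102] == 1.0
        assert p.loc[104] == 1.0

    def test_pooled_t_closed_form(self):
        """{1,2,3} vs {4,5,6}: t = -3.674 on 4 df, p from the t CDF."""
        values = pd.DataFrame(
            {f"s{i}": [v] for i, v in enumerate([1, 2, 3, 4, 5, 6], 1)},
            index=pd.Index([9], name="gene"),
        )
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(1, 7)],
                "compound": "X",
                "dose_level": "high",
                "time_h": 24,
                "role": ["treated"] * 3 + ["control"] * 3,
            }
        ).set_index("sample_id")
        p = run_diff_test(ExpressionMatrix(values, meta), "X", method="t_pooled")
        t_expected = -3.0 / math.sqrt(1.0 * (2 / 3))
        assert t_expected == pytest.approx(-3.674, abs=5e-4)
        assert p.loc[9] == pytest.approx(2 * stats.t.sf(abs(t_expected), 4), rel=1e-9)

    @pytest.mark.parametrize("method", ["t_pooled", "t_welch", "eb_moderated"])
    def test_null_pvalues_in_unit_interval(self, method):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng, n_genes=200)
        p = run_diff_test(m, "X", method=method)
        assert ((p >= 0) & (p <= 1)).all()

    def test_null_pvalues_uniform(self):
        """Pooled-t p-values under a 2,000-gene null look Uniform(0,1)."""
        rng = np.random.default_rng(42)
        m = _random_matrix(rng, n_genes=2000)
        p = run_diff_test(m, "X", method="t_pooled")
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_needs_two_samples_per_arm(self, tiny_expression):
        meta = tiny_expression.sample_meta
        keep = [s for s in meta.index if s not in ("cA_t2", "cA_t3")]
        m = ExpressionMatrix(tiny_expression.values[keep], meta.loc[keep])
        with pytest.raises(ValueError):
            run_diff_test(m, "A")


class TestAdjustBH:
    def test_step_up_by_hand(self):
        # hand-applied step-up: all become 0.04
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_single_p_identity(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            adjust_bh([0.01, float("nan")])

    @settings(derandomize=True, max_examples=100)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_matches_quadratic_reference(self, p):
        assert adjust_bh(p) == pytest.approx(bh_reference(p), rel=1e-10, abs=1e-12)

    def test_matches_reference_large_random(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.random(200)
            assert adjust_bh(p) == pytest.approx(bh_reference(p))


class TestCallDegs:
    def test_both_gates_must_pass(self, tiny_expression):
        table = call_degs(tiny_expression, "A", DEGParams(test_method="t_pooled"))
        thresh = math.log2(1.5)
        expected = (table["log2fc"].abs() >= thresh) & (table["fdr_q"] < 0.05)
        assert (table["is_deg"] == expected).all()

    def test_fc_gate_uses_exact_log2(self):
        params = DEGParams()
        assert params.log2_fc_threshold == math.log2(1.5)
        assert params.log2_fc_threshold != 0.585

    def test_gene_and_sample_order_invariance(self, tiny_expression):
        base = call_degs(tiny_expression, "A", DEGParams(test_method="t_pooled"))
        rng = np.random.default_rng(5)
        gene_perm = rng.permutation(tiny_expression.values.index)
        sample_perm = rng.permutation(tiny_expression.values.columns)
        shuffled = ExpressionMatrix(
            tiny_expression.values.loc[gene_perm, sample_perm],
            tiny_expression.sample_meta.loc[sample_perm],
        )
        table = call_degs(shuffled, "A", DEGParams(test_method="t_pooled")).loc[base.index]
        pd.testing.assert_frame_equal(table, base)

    def test_planted_effect_recovery(self):
        """50 planted 1.2-log2 effects at n=3/arm, sd 0.25 among 350 genes
        (the ~15% DEG density of the study conditions): >=45 recovered."""
        rng = np.random.default_rng(11)
        m, planted = _random_matrix(rng, n_genes=350, n_effects=50, effect=1.2, return_planted=True)
        table = call_degs(m, "X")
        assert table.loc[planted, "is_deg"].sum() >= 45

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DEGParams(fc_threshold=1.0)
        with pytest.raises(ValueError):
            DEGParams(fdr_alpha=0.0)
        with pytest.raises(ValueError):
            DEGParams(test_method="wilcoxon")


class TestUnionGroups:
    def _tables(self, sets):
        out = {}
        for name, genes in sets.items():
            idx = sorted(set.union(*sets.values()))
            out[name] = pd.DataFrame(
                {"is_deg": [g in genes for g in idx]}, index=pd.Index(idx, name="gene")
            )
        return out

    def test_union_within_group(self):
        tables = self._tables({"a": {1, 2}, "b": {2, 3}})
        result = union_group_degs(tables, {"a": "g1", "b": "g1"})
        assert result.per_group["g1"] == {1, 2, 3}

    def test_disjoint_groups(self):
        tables = self._tables({"a": {1}, "b": {2}})
        result = union_group_degs(tables, {"a": "g1", "b": "g2"})
        assert result.overall == {1, 2}

    def test_missing_group_label_raises(self):
        tables = self._tables({"a": {1}})
        with pytest.raises(ValueError):
            union_group_degs(tables, {})

    def test_matches_bruteforce_union(self):
        rng = np.random.default_rng(8)
        sets = {f"c{i}": set(map(int, rng.choice(50, rng.integers(1, 20), replace=False))) for i in range(10)}
        groups = {f"c{i}": ("g1" if i < 5 else "g2") for i in range(10)}
        result = union_group_degs(self._tables(sets), groups)
        brute = set()
        for s in sets.values():
            brute |= s
        assert result.overall == brute
        assert len(result.overall) <= sum(len(s) for s in sets.values())


def _random_matrix(rng, n_genes=500, n_effects=0, effect=0.0, sd=0.25, return_planted=False):
    genes = pd.Index(np.arange(1, n_genes + 1), name="gene")
    trt = rng.normal(7, sd, (n_genes, 3))
    ctl = rng.normal(7, sd, (n_genes, 3))
    planted = []
    if n_effects:
        planted = list(map(int, rng.choice(genes, n_effects, replace=False)))
        signs = rng.choice([-1.0, 1.0], n_effects)
        trt[np.array(planted) - 1] += (effect * signs)[:, None]
    values = pd.DataFrame(
        np.hstack([trt, ctl]),
        index=genes,
        columns=[f"t{i}" for i in range(3)] + [f"c{i}" for i in range(3)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": values.columns,
            "compound": "X",
            "dose_level": "high",
            "time_h": 24,
            "role": ["treated"] * 3 + ["control"] * 3,
        }
    ).set_index("sample_id")
    m = ExpressionMatrix(values, meta)
    return (m, planted) if return_planted else m
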