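"""Evidence matrix assembly, scoring, tiers, exclusivity flags."""

import numpy as np
import pandas as pd
import pytest

from darkgenes.annotation import DarknessCall
from darkgenes.evidence import (
    DEFAULT_SOURCES,
    TierParams,
    build_evidence_matrix,
    coverage_fraction,
    exclusivity_flags,
    score_and_tier,
)
from darkgenes.regulon_pathway import CompoundMapping
from darkgenes.xspecies import ModuleAssignment, OrthologMapping


def _calls(genes):
    return [DarknessCall(g, True, frozenset()) for g in genes]


def _degree_table(genes, degrees):
    frame = pd.DataFrame(degrees, index=pd.Index(genes, name="gene"))
    frame["n_snapshots_present"] = frame.notna().sum(axis=1).astype(int)
    return frame


def _literature(genes, **overrides):
    frame = pd.DataFrame(
        0,
        index=pd.Index(genes, name="gene"),
        columns=["n_diseases_curated", "n_diseases_all", "n_generifs", "n_publications"],
    )
    for col, values in overrides.items():
        for gene, v in values.items():
            frame.loc[gene, col] = v
    return frame


def _empty_ortho():
    return OrthologMapping(per_gene={}, rat_genes=set(), unmapped=set())


class TestBuildMatrix:
    def test_single_pin_flag(self):
        genes = [1, 2]
        matrix = build_evidence_matrix(
            _calls(genes),
            _degree_table(genes, {"BIANA": [3.0, np.nan], "HIPPIE": [np.nan, np.nan]}),
            _literature(genes),
            [], [], _empty_ortho(), ModuleAssignment(per_gene={}),
        )
        assert matrix.loc[1, "PIN_BIANA"]
        assert not matrix.loc[1, "PIN_HIPPIE"]
        assert matrix.loc[1].sum() == 1
        assert matrix.loc[2].sum() == 0

    def test_all_false_row(self):
        genes = [5]
        matrix = build_evidence_matrix(
            _calls(genes),
            _degree_table(genes, {"BIANA": [np.nan]}),
            _literature(genes),
            [], [], _empty_ortho(), ModuleAssignment(per_gene={}),
        )
        assert not matrix.loc[5].any()

    def test_gene_set_mismatch_raises(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            build_evidence_matrix(
                _calls([1, 2]),
                _degree_table([1], {"BIANA": [1.0]}),
                _literature([1, 2]),
                [], [], _empty_ortho(), ModuleAssignment(per_gene={}),
            )

    def test_twenty_gene_truth_table(self):
        """Matrix equals a hand-built truth table on a 20-gene fixture."""
        rng = np.random.default_rng(19)
        genes = list(range(1, 21))
        degrees = {
            name: [float(rng.integers(1, 9)) if rng.random() < 0.5 else np.nan for _ in genes]
            for name in ("BIANA", "HIPPIE", "INBIOMAP", "INTACT")
        }
        lit = _literature(
            genes,
            n_diseases_curated={g: int(rng.random() < 0.3) for g in genes},
            n_diseases_all={g: int(rng.random() < 0.5) * 2 for g in genes},
            n_generifs={g: int(rng.random() < 0.4) * 3 for g in genes},
            n_publications={g: int(rng.random() < 0.5) for g in genes},
        )
        reg_hit = set(map(int, rng.choice(genes, 6, replace=False)))
        sig_hit = set(map(int, rng.choice(genes, 4, replace=False)))
        reg = [CompoundMapping("c1", {"T"}, reg_hit)] if reg_hit else []
        sig = [CompoundMapping("c1", {"P"}, sig_hit)] if sig_hit else []
        ortho_genes = set(map(int, rng.choice(genes, 10, replace=False)))
        ortho = OrthologMapping(
            per_gene={g: [f"r{g}"] for g in ortho_genes},
            rat_genes={f"r{g}" for g in ortho_genes},
            unmapped=set(genes) - ortho_genes,
        )
        module_genes = {f"r{g}" for g in rng.choice(sorted(ortho_genes), 5, replace=False)}
        assignment = ModuleAssignment(
            per_gene={r: (["1"] if r in module_genes else []) for r in ortho.rat_genes}
        )
        matrix = build_evidence_matrix(
            _calls(genes), _degree_table(genes, degrees), lit, reg, sig, ortho, assignment
        )
        for i, g in enumerate(genes):
            assert matrix.loc[g, "PIN_BIANA"] == (not np.isnan(degrees["BIANA"][i]))
            assert matrix.loc[g, "DISEASE_CURATED"] == (lit.loc[g, "n_diseases_curated"] >= 1)
            assert matrix.loc[g, "DISEASE_ALL"] == (lit.loc[g, "n_diseases_all"] >= 1)
            assert matrix.loc[g, "GENERIF"] == (lit.loc[g, "n_generifs"] >= 1)
            assert matrix.loc[g, "PUBTATOR"] == (lit.loc[g, "n_publications"] >= 1)
            assert matrix.loc[g, "REGULON"] == (g in reg_hit)
            assert matrix.loc[g, "SIGNATURE"] == (g in sig_hit)
            assert matrix.loc[g, "RAT_ORTHOLOG"] == (g in ortho_genes)
            assert matrix.loc[g, "WGCNA_MODULE"] == (f"r{g}" in module_genes)


class TestScoreAndTier:
    def _matrix(self, n_flags, n_sources=12):
        row = [True] * n_flags + [False] * (n_sources - n_flags)
        return pd.DataFrame([row], index=[1], columns=list(DEFAULT_SOURCES))

    @pytest.mark.parametrize("n,tier", [(8, "high"), (12, "high"), (4, "moderate"),
                                        (7, "moderate"), (1, "low"), (3, "low"), (0, "none")])
    def test_tier_thresholds(self, n, tier):
        summary = score_and_tier(self._matrix(n))
        assert summary.loc[1, "score"] == n
        assert summary.loc[1, "tier"] == tier

    def test_score_equals_row_sum_random(self):
        rng = np.random.default_rng(23)
        matrix = pd.DataFrame(
            rng.random((50, 12)) < 0.4, columns=list(DEFAULT_SOURCES),
            index=pd.Index(range(50), name="gene"),
        )
        summary = score_and_tier(matrix)
        expected = matrix.to_numpy().sum(axis=1)
        assert (summary["score"].to_numpy() == expected).all()

    def test_tier_monotone_in_score(self):
        order = {"none": 0, "low": 1, "moderate": 2, "high": 3}
        tiers = [order[TierParams().tier_of(s)] for s in range(13)]
        assert tiers == sorted(tiers)

    def test_adding_source_never_lowers_tier(self):
        rng = np.random.default_rng(24)
        order = {"none": 0, "low": 1, "moderate": 2, "high": 3}
        matrix = pd.DataFrame(
            rng.random((30, 12)) < 0.4, columns=list(DEFAULT_SOURCES),
            index=pd.Index(range(30), name="gene"),
        )
        before = score_and_tier(matrix)
        extended = matrix.copy()
        extended["EXTRA"] = True
        after = score_and_tier(extended)
        for g in matrix.index:
            assert order[after.loc[g, "tier"]] >= order[before.loc[g, "tier"]]


class TestExclusivity:
    def _tables(self, deg_map, genes=(1,)):
        tables = {}
        for compound, deg_genes in deg_map.items():
            idx = pd.Index(sorted(genes), name="gene")
            tables[compound] = pd.DataFrame({"is_deg": [g in deg_genes for g in idx]}, index=idx)
        return tables

    def _groups(self):
        groups = {f"M{i}": "most_dili" for i in range(1, 6)}
        groups.update({f"N{i}": "no_dili" for i in range(1, 6)})
        return groups

    def test_deg_in_4of5_and_no_contamination(self):
        deg_map = {c: {1} for c in ["M1", "M2", "M3", "M4"]}
        deg_map.update({c: set() for c in ["M5", "N1", "N2", "N3", "N4", "N5"]})
        flags = exclusivity_flags(self._tables(deg_map), self._groups(), [1])
        assert flags.loc[1, "most_dili_exclusive"]
        assert flags.loc[1, "deg_in_4of5_dili"]

    def test_no_dili_contamination_clears_both(self):
        deg_map = {c: {1} for c in ["M1", "M2", "M3", "M4", "M5", "N1"]}
        deg_map.update({c: set() for c in ["N2", "N3", "N4", "N5"]})
        flags = exclusivity_flags(self._tables(deg_map), self._groups(), [1])
        assert not flags.loc[1, "most_dili_exclusive"]
        assert not flags.loc[1, "deg_in_4of5_dili"]

    def test_single_dili_compound(self):
        deg_map = {c: set() for c in self._groups()}
        deg_map["M1"] = {1}
        flags = exclusivity_flags(self._tables(deg_map), self._groups(), [1])
        assert flags.loc[1, "most_dili_exclusive"]
        assert not flags.loc[1, "deg_in_4of5_dili"]

    def test_4of5_implies_exclusive_random(self):
        rng = np.random.default_rng(27)
        genes = list(range(20))
        deg_map = {
            c: set(map(int, rng.choice(genes, 8, replace=False))) for c in self._groups()
        }
        flags = exclusivity_flags(self._tables(deg_map, genes), self._groups(), genes)
        implied = ~flags["deg_in_4of5_dili"] | flags["most_dili_exclusive"]
        assert implied.all()

    def test_missing_table_raises(self):
        with pytest.raises(ValueError):
            exclusivity_flags({}, self._groups(), [1])


class TestCoverageFraction:
    def test_three_of_four(self):
        matrix = pd.DataFrame(
            {"A": [True, True, True, False], "B": [False] * 4},
            index=pd.Index(range(4), name="gene"),
        )
        frac, pct = coverage_fraction(matrix)
        assert frac == pytest.approx(0.75)
        assert pct == 75

    def test_all_false(self):
        matrix = pd.DataFrame({"A": [False, False]}, index=[1, 2])
        assert coverage_fraction(matrix) == (0.0, 0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            coverage_fraction(pd.DataFrame())
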