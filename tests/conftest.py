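import logging

import pandas as pd
import pytest

from darkgenes.idmap import GeneCatalog, GeneRecord
from darkgenes.pipeline import RunConfig, run_all
from darkgenes.synthetic_data import WorldConfig, simulate_world

logging.getLogger("darkgenes").setLevel(logging.ERROR)


@pytest.fixture
def toy_catalog() -> GeneCatalog:
    """Four records exercising every step of the mapping cascade."""
    return GeneCatalog(
        [
            GeneRecord(1, "ALPHA", frozenset({"A1", "SHARED"}), frozenset({"P10001"}), "protein_coding"),
            GeneRecord(2, "BETA", frozenset({"B1", "SHARED"}), frozenset({"P10002"}), "lincRNA"),
            GeneRecord(3, "GAMMA", frozenset({"G1"}), frozenset(), "pseudogene"),
            GeneRecord(4, "A1", frozenset(), frozenset(), "unknown"),  # symbol colliding with a synonym
        ]
    )


@pytest.fixture
def tiny_expression():
    """Two compounds, 3 treated + 3 control samples each, 4 genes."""
    from darkgenes.diffexpr import ExpressionMatrix

    values = pd.DataFrame(
        {
            "cA_t1": [5.585, 4.0, 6.0, 7.0],
            "cA_t2": [5.585, 4.0, 6.1, 7.1],
            "cA_t3": [5.585, 4.0, 5.9, 6.9],
            "cA_c1": [5.0, 6.0, 6.0, 7.05],
            "cA_c2": [5.0, 6.0, 6.1, 7.0],
            "cA_c3": [5.0, 6.0, 5.9, 6.95],
            "cB_t1": [1.0, 2.0, 3.0, 1.0],
            "cB_t2": [2.0, 2.0, 3.0, 1.0],
            "cB_t3": [3.0, 2.0, 3.0, 1.0],
            "cB_c1": [4.0, 2.0, 3.0, 1.0],
            "cB_c2": [5.0, 2.0, 3.0, 1.0],
            "cB_c3": [6.0, 2.0, 3.0, 1.0],
        },
        index=pd.Index([101, 102, 103, 104], name="gene"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": list(values.columns),
            "compound": ["A"] * 6 + ["B"] * 6,
            "dose_level": "high",
            "time_h": 24,
            "role": (["treated"] * 3 + ["control"] * 3) * 2,
            "group": ["most_dili"] * 6 + ["no_dili"] * 6,
        }
    ).set_index("sample_id")
    return ExpressionMatrix(values, meta)


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """The default synthetic world (seed 7), simulated once per session."""
    outdir = tmp_path_factory.mktemp("world")
    config = WorldConfig(seed=7)
    paths, truth = simulate_world(config, outdir)
    return config, paths, truth, outdir


@pytest.fixture(scope="session")
def default_run(default_world, tmp_path_factory):
    """Full pipeline run over the default world."""
    _, _, _, indir = default_world
    outdir = tmp_path_factory.mktemp("bundle")
    result = run_all(RunConfig(indir=indir, outdir=outdir))
    return result
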