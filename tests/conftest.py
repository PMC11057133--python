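import numpy as np
import pandas as pd
import pytest

import coexage as cx
from coexage.pipeline import RunConfig, build_condition_modules, preprocess


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests."""
    return cx.simulate_cohort(cx.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def built(cohort):
    """Preprocessed expression plus detected modules/TOM for both conditions."""
    cfg = RunConfig(seed=7)
    expr, tumor_ids, normal_ids = preprocess(cohort.expression, cfg)
    mods, toms = {}, {}
    for tag, ids in (("tumor", tumor_ids), ("normal", normal_ids)):
        mods[tag], toms[tag] = build_condition_modules(expr, ids, cfg, tag)
    return {
        "expr": expr,
        "tumor_ids": tumor_ids,
        "normal_ids": normal_ids,
        "modules": mods,
        "toms": toms,
    }


def random_symmetric_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def toy_expression(values: np.ndarray, genes=None, samples=None, meta=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cx.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)
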