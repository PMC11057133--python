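import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coexage as cx
from coexage.network import (
    CoexpressionNetwork,
    adjacency,
    cpm_filter,
    detect_modules,
    drop_bad_genes,
    extract_module_network,
    remove_outlier_samples,
    tom,
)

from conftest import random_symmetric_adjacency, toy_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


# ---------------------------------------------------------------------------
# preprocessing


def test_cpm_filter_all_tumor_or_all_normal_rule():
    # 3 genes x 4 samples; library sizes made equal so CPM is proportional
    vals = np.array(
        [
            [300.0, 300, 0, 0],  # high in all tumors, zero in normals -> kept
            [0.1, 0.1, 0.1, 0.1],  # low everywhere -> dropped
            [300.0, 0.0, 300.0, 0.0],  # fails one sample in each group -> dropped
        ]
    )
    vals = np.vstack([vals, 1e6 - vals.sum(axis=0)])  # filler gene equalizes libraries
    expr = toy_expression(vals, genes=["hi_t", "low", "spotty", "fill"])
    kept = cpm_filter(expr, tumor_ids=["s0", "s1"], normal_ids=["s2", "s3"])
    assert "hi_t" in kept and "low" not in kept and "spotty" not in kept


def test_cpm_filter_rejects_empty_group():
    expr = toy_expression(np.ones((2, 3)))
    with pytest.raises(ValueError):
        cpm_filter(expr, tumor_ids=[], normal_ids=["s0"])


def test_outlier_sample_and_its_pair_removed(rng):
    # 12 samples: a lone extreme sample is only detectable once there are
    # enough merge heights for its z-score to clear 2.5 (needs >= 9 samples).
    base = rng.normal(10, 1, size=(50, 12))
    base[:, 3] += 100.0  # sample s3 far from everything
    meta = pd.DataFrame(
        {
            "condition": ["tumor"] * 6 + ["normal"] * 6,
            "pair_id": [f"p{j}" for j in range(6)] * 2,
        },
        index=[f"s{j}" for j in range(12)],
    )
    expr = toy_expression(np.abs(base), meta=meta)
    cleaned = remove_outlier_samples(expr)
    assert "s3" not in cleaned.samples
    assert "s9" not in cleaned.samples  # its pair
    assert len(cleaned.samples) == 10


def test_identical_replicates_keep_all_samples():
    vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 5))
    cleaned = remove_outlier_samples(toy_expression(vals))
    assert list(cleaned.samples) == [f"s{j}" for j in range(5)]


def test_drop_bad_genes_removes_constant_and_mostly_missing():
    vals = pd.DataFrame(
        {
            "s0": [1.0, 5.0, np.nan, 1.0],
            "s1": [1.0, 6.0, np.nan, 2.0],
            "s2": [1.0, 7.0, np.nan, 3.0],
            "s3": [1.0, 8.0, 4.0, 4.0],
            "s4": [1.0, 9.0, 5.0, 5.0],
        },
        index=["const", "fine", "missing60", "fine2"],
    )
    expr = cx.ExpressionMatrix(vals.clip(lower=0))
    kept = drop_bad_genes(expr, max_missing=0.5)
    assert list(kept.genes) == ["fine", "fine2"]


# ---------------------------------------------------------------------------
# adjacency and TOM


def test_adjacency_identical_and_opposite_profiles_are_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    vals = np.vstack([x, 2 * x + 1, 10 - x])  # identical, scaled, anti-correlated
    net = adjacency(toy_expression(vals), beta=6)
    assert net.weights[0, 1] == pytest.approx(1.0)
    assert net.weights[0, 2] == pytest.approx(1.0)  # unsigned network


def test_adjacency_matches_brute_force_power_of_correlation(rng):
    vals = rng.uniform(1, 100, size=(3, 4))
    net = adjacency(toy_expression(vals), beta=6)
    for i in range(3):
        for j in range(3):
            r = np.corrcoef(vals[i], vals[j])[0, 1]
            assert net.weights[i, j] == pytest.approx(abs(r) ** 6 if i != j else 1.0, abs=1e-12)


def test_adjacency_rejects_zero_variance_gene():
    vals = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError, match="g0"):
        adjacency(toy_expression(vals))


def test_tom_complete_graph_is_one():
    a = np.ones((3, 3))
    net = CoexpressionNetwork(["a", "b", "c"], a, kind="adjacency", beta=1)
    t = tom(net)
    assert np.allclose(t.weights, 1.0)


def test_tom_zero_edge_no_common_neighbor_is_zero():
    a = np.eye(4)
    a[0, 1] = a[1, 0] = 0.8  # isolated pair; genes 2,3 disconnected
    net = CoexpressionNetwork(list("abcd"), a, kind="adjacency", beta=1)
    t = tom(net)
    assert t.weights[2, 3] == pytest.approx(0.0)
    assert t.weights[0, 2] == pytest.approx(0.0)


def test_tom_matches_triple_loop_oracle(rng):
    a = random_symmetric_adjacency(6, rng)
    net = CoexpressionNetwork([f"g{i}" for i in range(6)], a, kind="adjacency", beta=1)
    assert np.allclose(tom(net).weights, brute_force_tom(a), atol=1e-12)


def test_tom_rejects_asymmetric_input():
    a = np.eye(3)
    a[0, 1] = 0.5
    net = CoexpressionNetwork(list("abc"), a, kind="adjacency", beta=1)
    with pytest.raises(ValueError):
        tom(net)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 0.3))
def test_tom_monotone_in_any_edge(seed, bump):
    """Raising one off-diagonal adjacency never lowers that pair's overlap."""
    rng = np.random.default_rng(seed)
    a = random_symmetric_adjacency(5, rng) * 0.7
    np.fill_diagonal(a, 1.0)
    genes = [f"g{i}" for i in range(5)]
    t0 = tom(CoexpressionNetwork(genes, a, "adjacency", 1)).weights
    a2 = a.copy()
    a2[0, 1] = a2[1, 0] = min(1.0, a[0, 1] + bump)
    t1 = tom(CoexpressionNetwork(genes, a2, "adjacency", 1)).weights
    assert t1[0, 1] >= t0[0, 1] - 1e-12


def test_permutation_equivariance(rng):
    """Permuting gene order permutes adjacency/TOM and leaves modules intact."""
    vals = rng.normal(10, 2, size=(8, 12)) ** 2
    expr = toy_expression(vals)
    perm = rng.permutation(8)
    expr_p = toy_expression(vals[perm], genes=[f"g{i}" for i in perm])
    t = tom(adjacency(expr)).to_frame()
    t_p = tom(adjacency(expr_p)).to_frame()
    assert np.allclose(t.loc[t_p.index, t_p.columns].to_numpy(), t_p.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# module detection


def _block_tom(sizes, within=0.6, between=0.01, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    w = np.full((n, n), between) + rng.uniform(0, 0.005, (n, n))
    w = (w + w.T) / 2
    start = 0
    for s in sizes:
        w[start : start + s, start : start + s] = within + rng.uniform(
            0, 0.05, (s, s)
        )
        start += s
    w = (w + w.T) / 2
    np.clip(w, 0, 1, out=w)
    np.fill_diagonal(w, 1.0)
    return CoexpressionNetwork([f"g{i}" for i in range(n)], w, kind="tom", beta=6)


def test_detect_modules_recovers_two_planted_blocks():
    net = _block_tom([12, 10])
    mods = detect_modules(net, min_size=8)
    assert len(mods.modules) == 2
    assert mods.modules["M1"] == {f"g{i}" for i in range(12)}
    assert mods.modules["M2"] == {f"g{i}" for i in range(12, 22)}


def test_detect_modules_single_factor_plus_noise():
    """One latent factor drives 20 genes; 20 noise genes land in grey."""
    rng = np.random.default_rng(3)
    f = rng.normal(0, 1, 30)
    sig = 8 + 1.5 * f[None, :] + rng.normal(0, 0.3, size=(20, 30))
    noise = rng.normal(8, 1, size=(20, 30))
    net = tom(adjacency(toy_expression(np.abs(np.vstack([sig, noise]))), beta=6))
    mods = detect_modules(net, min_size=10)
    assert len(mods.modules) == 1
    signal = {f"g{i}" for i in range(20)}
    assert signal <= mods.modules["M1"]
    assert len(mods.modules["M1"] - signal) <= 5  # little noise contamination


def test_detect_modules_noise_goes_all_grey(rng):
    """Independent genes produce no cluster of min size: everything grey."""
    vals = rng.normal(8, 1, size=(40, 30)) ** 2
    net = tom(adjacency(toy_expression(vals), beta=6))
    mods = detect_modules(net, min_size=30)
    assert not mods.modules
    assert len(mods.grey) == 40


def test_detect_modules_deterministic_and_order_invariant(rng):
    net = _block_tom([12, 10, 9])
    m1 = detect_modules(net, min_size=8)
    m2 = detect_modules(net, min_size=8)
    assert m1.modules == m2.modules
    perm = rng.permutation(len(net.genes))
    net_p = CoexpressionNetwork(
        [net.genes[i] for i in perm], net.weights[np.ix_(perm, perm)], "tom", 6
    )
    m3 = detect_modules(net_p, min_size=8)
    assert {frozenset(g) for g in m1.modules.values()} == {
        frozenset(g) for g in m3.modules.values()
    }


# ---------------------------------------------------------------------------
# sub-networks


def test_extract_module_network_identity_and_singleton(rng):
    a = random_symmetric_adjacency(5, rng)
    net = CoexpressionNetwork([f"g{i}" for i in range(5)], a, "adjacency", 6)
    full = extract_module_network(net, net.genes)
    assert np.allclose(full.to_numpy(), a)
    single = extract_module_network(net, ["g2"])
    assert single.shape == (1, 1) and single.iloc[0, 0] == 1.0


def test_extract_module_network_matches_parent_entries(rng):
    a = random_symmetric_adjacency(5, rng)
    net = CoexpressionNetwork([f"g{i}" for i in range(5)], a, "adjacency", 6)
    sub = extract_module_network(net, ["g4", "g0", "g2"])
    for gi in sub.index:
        for gj in sub.columns:
            i, j = int(gi[1]), int(gj[1])
            assert sub.loc[gi, gj] == a[i, j]
    with pytest.raises(ValueError):
        extract_module_network(net, ["nope"])
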