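from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meioscreen import MultiomeError, bh_fdr, call_differential, rank_sum_test


def exact_ranksum_oracle(a, b):
    """Two-sided exact p by full enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    mu = n_a * len(b) / 2.0

    def u_stat(idx_a):
        r = ranks[list(idx_a)].sum()
        return r - n_a * (n_a + 1) / 2.0

    u_obs = u_stat(range(n_a))
    us = np.array([u_stat(c) for c in combinations(range(len(pooled)), n_a)])
    return float(np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12))


def bh_oracle(p):
    """O(m^2) direct application of the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    for i in range(m):
        q[i] = min(min(m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0)
    return q


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=40))
    def test_bh_property_matches_oracle_and_stays_in_unit_interval(p):
        q = bh_fdr(p)
        assert np.all((q >= 0) & (q <= 1))
        assert np.allclose(q, bh_oracle(p), atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=2,
                    max_size=8),
           st.lists(st.integers(min_value=0, max_value=9), min_size=2,
                    max_size=8))
    def test_rank_sum_p_is_symmetric_and_valid(a, b):
        _, p_ab = rank_sum_test(a, b)
        _, p_ba = rank_sum_test(b, a)
        assert 0.0 <= p_ab <= 1.0
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_identical_groups_give_p_one():
    _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert p == 1.0


def test_exact_p_matches_enumeration_of_all_20_splits():
    a, b = [1, 2, 3], [4, 5, 6]
    _, p = rank_sum_test(a, b)
    assert p == pytest.approx(2 / 20)
    assert p == pytest.approx(exact_ranksum_oracle(a, b))


@pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (5, 5), (5, 4)])
def test_exact_p_equals_enumeration_for_small_groups(n_a, n_b):
    rng = np.random.default_rng(n_a * 10 + n_b)
    for _ in range(5):
        pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
        a, b = pooled[:n_a], pooled[n_a:]
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_ranksum_oracle(a, b), abs=1e-12)


def test_rejection_rate_calibrated_under_null():
    """50 vs 50 standard-normal draws, 1,000 replicates, alpha = 0.05."""
    rng = np.random.default_rng(42)
    from scipy.stats import mannwhitneyu
    A = rng.standard_normal((50, 1000))
    B = rng.standard_normal((50, 1000))
    p = mannwhitneyu(A, B, alternative="two-sided", method="asymptotic",
                     axis=0).pvalue
    rate = (p <= 0.05).mean()
    assert 0.035 <= rate <= 0.065


def test_normal_approximation_close_to_exact_on_small_samples():
    rng = np.random.default_rng(3)
    from scipy.stats import mannwhitneyu
    for _ in range(20):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        p_exact = mannwhitneyu(a, b, method="exact").pvalue
        p_norm = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.06


def test_empty_group_rejected():
    with pytest.raises(MultiomeError):
        rank_sum_test([], [1.0])


def test_bh_single_p_is_identity():
    assert bh_fdr([0.05])[0] == pytest.approx(0.05)


def test_bh_hand_worked_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_quadratic_oracle():
    rng = np.random.default_rng(8)
    for _ in range(5):
        p = rng.uniform(size=37)
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(MultiomeError):
        bh_fdr([0.5, 1.2])


def _toy_norm(seed=0, n_cells=40, n_features=30, shift_features=(0, 1)):
    rng = np.random.default_rng(seed)
    X = rng.normal(1.0, 0.2, size=(n_cells, n_features)).clip(min=0)
    stages = ["preleptotene"] * (n_cells // 2) + ["leptotene"] * (n_cells // 2)
    for f in shift_features:
        X[n_cells // 2:, f] += 2.0
    cells = pd.DataFrame({"stage": stages})
    return X, cells


def test_group_swap_negates_lfc_and_swaps_directions():
    X, cells = _toy_norm()
    fwd = call_differential(X, cells, "preleptotene", "leptotene")
    rev = call_differential(X, cells, "leptotene", "preleptotene")
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
    assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-12)
    up, down = fwd["direction"] == "up", fwd["direction"] == "down"
    assert (rev.loc[up, "direction"] == "down").all()
    assert (rev.loc[down, "direction"] == "up").all()


def test_calls_invariant_to_cell_permutation():
    X, cells = _toy_norm(seed=5)
    rng = np.random.default_rng(9)
    perm = rng.permutation(len(cells))
    base = call_differential(X, cells, "preleptotene", "leptotene")
    shuf = call_differential(X[perm], cells.iloc[perm].reset_index(drop=True),
                             "preleptotene", "leptotene")
    assert np.allclose(base["log2fc"], shuf["log2fc"], atol=1e-12)
    assert (base["direction"] == shuf["direction"]).all()


def test_constant_feature_is_ns_with_zero_lfc():
    X, cells = _toy_norm()
    X[:, 5] = 2.5
    out = call_differential(X, cells, "preleptotene", "leptotene")
    assert out.loc[5, "direction"] == "ns"
    assert out.loc[5, "log2fc"] == 0.0
    assert out.loc[5, "p_value"] == 1.0


def test_missing_stage_error_names_available_stages():
    X, cells = _toy_norm()
    with pytest.raises(MultiomeError, match="preleptotene"):
        call_differential(X, cells, "mitotic", "leptotene")


def test_directions_respect_thresholds_and_signs():
    X, cells = _toy_norm(seed=2, shift_features=(0,))
    out = call_differential(X, cells, "preleptotene", "leptotene",
                            lfc_thresh=0.25, q_thresh=0.05)
    assert out.loc[0, "direction"] == "up"
    assert (out.loc[out["direction"] == "up", "log2fc"] > 0).all()
    assert (out.loc[out["direction"] == "down", "log2fc"] < 0).all()
    ns = out["direction"] == "ns"
    assert ((np.abs(out.loc[ns, "log2fc"]) < 0.25)
            | (out.loc[ns, "q_value"] > 0.05)).all()
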