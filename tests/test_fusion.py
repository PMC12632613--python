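"""Rank maps, fusion matrices, sparsity projection and the fused WLS solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlscp.cox import EPS_WEIGHT
from tlscp.fusion import (FusionMatrix, PenaltySpec, RankMap,
                          build_fusion_matrix, build_rank_map,
                          project_sparsity, solve_fused_wls)


class TestRankMap:
    @pytest.mark.parametrize("beta, order", [
        ([-1.0, 0.0, 2.0], [0, 1, 2]),
        ([0.5, -1.0, 2.0], [1, 0, 2]),
        ([0.0, 0.0, -1.0], [2, 0, 1]),  # first-occurrence tie-break
    ])
    def test_ordering(self, beta, order):
        assert build_rank_map(beta).order.tolist() == order

    def test_applied_order_is_nondecreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = rng.choice([-1.0, 0.0, 0.5, 2.0], size=9)
            tau = build_rank_map(beta)
            assert np.all(np.diff(beta[tau.order]) >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_rank_map([np.inf, 0.0])
        with pytest.raises(ValueError):
            RankMap(order=np.array([0, 0, 1]))

    def test_ranks_inverse(self):
        tau = build_rank_map([0.5, -1.0, 2.0])
        assert tau.ranks().tolist() == [2, 1, 3]


class TestFusionMatrix:
    def test_rows_are_signed_incidence(self):
        tau = build_rank_map([0.5, -1.0, 2.0])
        D = build_fusion_matrix(tau)
        beta = np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(D.rows @ beta, [-1.5, -1.5])
        assert np.all(D.rows.sum(axis=1) == 0)
        assert np.all(np.sort(np.abs(D.rows), axis=1)[:, -2:] == 1)
        assert np.linalg.matrix_rank(D.rows) == 2

    def test_constant_vector_in_null_space(self):
        tau = build_rank_map(np.random.default_rng(3).normal(size=7))
        D = build_fusion_matrix(tau)
        np.testing.assert_allclose(D.rows @ np.full(7, 3.3), 0.0, atol=1e-12)

    def test_single_coefficient_is_an_error(self):
        with pytest.raises(ValueError):
            build_fusion_matrix(RankMap(order=np.array([0])))

    def test_cluster_count_equals_nonzero_differences_plus_one(self):
        # when tau sorts beta, ||D beta||_0 + 1 counts the distinct values
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = int(rng.integers(2, 12))
            beta = rng.choice([-1.0, 0.5, 2.0, 2.0], size=p)
            tau = build_rank_map(beta)
            D = build_fusion_matrix(tau)
            nnz = np.count_nonzero(D.rows @ beta)
            assert nnz + 1 == len(np.unique(beta))

    def test_triplet_dump(self):
        D = build_fusion_matrix(build_rank_map([1.0, 0.0]))
        assert sorted(D.to_triplets()) == [(0, 0, -1.0), (0, 1, 1.0)]


class TestProjectSparsity:
    @pytest.mark.parametrize("v, k, expected", [
        ([3.0, -1.0, 0.5], 1, [3.0, 0.0, 0.0]),
        ([3.0, -1.0, 0.5], 5, [3.0, -1.0, 0.5]),
        ([2.0, -2.0, 1.0], 1, [2.0, 0.0, 0.0]),  # magnitude tie keeps lower index
    ])
    def test_examples(self, v, k, expected):
        np.testing.assert_allclose(project_sparsity(v, k), expected)

    def test_tie_projection_is_optimal_by_brute_force(self):
        v = np.array([2.0, -2.0, 1.0])
        proj = project_sparsity(v, 1)
        dists = []
        for keep in range(3):
            z = np.zeros(3)
            z[keep] = v[keep]
            dists.append(np.linalg.norm(v - z))
        assert np.linalg.norm(v - proj) == pytest.approx(min(dists))

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8),
           st.integers(1, 8))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_idempotent_and_distance_optimal(self, v, k):
        v = np.asarray(v)
        proj = project_sparsity(v, k)
        assert np.count_nonzero(proj) <= k
        np.testing.assert_array_equal(project_sparsity(proj, k), proj)
        # no other size-k support is closer (exhaustive over supports)
        from itertools import combinations
        best = min(
            (np.linalg.norm(v - np.where(np.isin(np.arange(v.size), s), v, 0.0))
             for r in range(min(k, v.size) + 1)
             for s in combinations(range(v.size), r)),
        )
        assert np.linalg.norm(v - proj) == pytest.approx(best, abs=1e-12)

    def test_bad_k(self):
        with pytest.raises(ValueError):
            project_sparsity([1.0], 0)


def _wls_instance(seed, n=40, p=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta_true = rng.choice([-1.0, 1.0], size=p)
    z = X @ beta_true + rng.normal(scale=0.3, size=n)
    w = rng.uniform(0.2, 1.0, size=n)
    return X, z, w


def _wls_solution(X, z, w):
    n = X.shape[0]
    Xw = X * (w / n)[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T @ z)


def _quad_objective(X, z, w, beta):
    n = X.shape[0]
    r = z - X @ beta
    return 0.5 * float(np.sum(w / n * r**2))


class TestSolveFusedWLS:
    def test_vacuous_constraint_equals_wls(self):
        X, z, w = _wls_instance(0)
        tau = build_rank_map(np.arange(4.0))
        D = build_fusion_matrix(tau)
        spec = PenaltySpec(family="distance", k=3)
        beta = solve_fused_wls(X, z, w, D, spec, np.zeros(4))
        np.testing.assert_allclose(beta, _wls_solution(X, z, w), atol=1e-8)

    def test_vanishing_shrinkage_equals_wls(self):
        X, z, w = _wls_instance(1)
        tau = build_rank_map(np.arange(4.0))
        D = build_fusion_matrix(tau)
        spec = PenaltySpec(family="lasso", lam=1e-12)
        beta = solve_fused_wls(X, z, w, D, spec, np.zeros(4))
        np.testing.assert_allclose(beta, _wls_solution(X, z, w), atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_k1_matches_exhaustive_pattern_oracle(self, seed):
        # p=4, k=1: the attained objective equals the best of the three
        # contiguous single-break patterns, each refit by constrained WLS
        X, z, w = _wls_instance(seed, n=60, p=4)
        prelim = _wls_solution(X, z, w)
        tau = build_rank_map(prelim)
        D = build_fusion_matrix(tau)
        spec = PenaltySpec(family="distance", k=1)
        beta = solve_fused_wls(X, z, w, D, spec, prelim)
        best = np.inf
        for brk in (1, 2, 3):
            M = np.zeros((4, 2))
            M[tau.order[:brk], 0] = 1.0
            M[tau.order[brk:], 1] = 1.0
            gamma = _wls_solution(X @ M, z, w)
            best = min(best, _quad_objective(X, z, w, M @ gamma))
        assert _quad_objective(X, z, w, beta) == pytest.approx(best, abs=1e-6)

    def test_fused_result_is_exactly_cluster_constant(self):
        X, z, w = _wls_instance(2, n=80, p=6)
        prelim = _wls_solution(X, z, w)
        tau = build_rank_map(prelim)
        D = build_fusion_matrix(tau)
        beta = solve_fused_wls(X, z, w, D,
                               PenaltySpec(family="distance", k=2), prelim)
        assert len(np.unique(beta)) <= 3
        assert np.count_nonzero(D.rows @ beta) <= 2

    @pytest.mark.parametrize("family", ["lasso", "scad", "mcp"])
    def test_shrinkage_families_fuse_under_heavy_penalty(self, family):
        X, z, w = _wls_instance(3, n=80, p=5)
        prelim = _wls_solution(X, z, w)
        tau = build_rank_map(prelim)
        D = build_fusion_matrix(tau)
        spec = PenaltySpec(family=family, lam=50.0)
        beta = solve_fused_wls(X, z, w, D, spec, prelim)
        assert len(np.unique(beta)) == 1  # everything fused

    def test_anneal_objective_trace_monotone_at_fixed_lambda(self):
        X, z, w = _wls_instance(4, n=60, p=6)
        prelim = _wls_solution(X, z, w)
        tau = build_rank_map(prelim)
        D = build_fusion_matrix(tau)
        info = {}
        solve_fused_wls(X, z, w, D, PenaltySpec(family="distance", k=2),
                        prelim, info=info)
        trace = info["trace"]
        assert len(trace) > 1
        for (lam_a, obj_a), (lam_b, obj_b) in zip(trace, trace[1:]):
            if lam_a == lam_b:  # MM steps at a fixed lambda must descend
                assert obj_b <= obj_a + 1e-9

    def test_unpenalized_columns_stay_free(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 5))
        z = X @ np.array([1.0, 1.0, -1.0, -1.0, 3.0]) + rng.normal(scale=0.1, size=100)
        w = np.ones(100)
        tau = build_rank_map(np.array([1.0, 1.0, -1.0, -1.0]))
        D = build_fusion_matrix(tau)
        beta = solve_fused_wls(X, z, w, D, PenaltySpec(family="distance", k=1),
                               np.zeros(5), penalized_cols=[0, 1, 2, 3],
                               unpenalized_cols=(4,))
        assert beta[0] == beta[1] and beta[2] == beta[3]
        assert beta[4] == pytest.approx(3.0, abs=0.1)


class TestPenaltySpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PenaltySpec(family="nope", k=1)
        with pytest.raises(ValueError):
            PenaltySpec(family="distance")
        with pytest.raises(ValueError):
            PenaltySpec(family="lasso")
        with pytest.raises(ValueError):
            PenaltySpec(family="distance", k=1, sched_growth=0.9)
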