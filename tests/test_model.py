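import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmvc import (
    LatentFactors,
    ModelConfig,
    ProteinUniverse,
    WeightedNetworkView,
    discretize,
    extract_complexes,
    fit,
    masked_kl,
    objective,
    split_latent_dims,
    update_shared,
    update_specific,
)
from psmvc.model import MONOTONE_RTOL

from conftest import make_random_factors, make_random_view, raw_view
from oracles import (
    discretize_row_brute,
    masked_kl_loop,
    objective_loop,
    update_shared_loop,
    update_specific_loop,
)


def make_instance(rng, n=5, k_c=2, k_s=2, coverage=0.8):
    uni = ProteinUniverse([f"P{i}" for i in range(n)])
    views = (
        make_random_view(rng, uni, coverage=coverage),
        make_random_view(rng, uni, coverage=coverage),
    )
    return views, make_random_factors(rng, n, k_c, k_s)


class TestSplitLatentDims:
    @pytest.mark.parametrize(
        "K,eta,expected",
        [(8, 0.5, (4, 2)), (8, 1.0, (8, 0)), (8, 0.0, (0, 4)), (10, 0.5, (6, 2))],
    )
    def test_examples(self, K, eta, expected):
        assert split_latent_dims(K, eta) == expected

    @given(st.integers(1, 500), st.floats(0.0, 1.0))
    @settings(deadline=None)
    def test_partition_identity(self, K, eta):
        k_c, k_s = split_latent_dims(K, eta)
        assert k_c >= 0 and k_s >= 0
        assert k_c + 2 * k_s == K


class TestMaskedKL:
    def test_zero_when_reconstruction_matches(self, rng, small_universe):
        v = make_random_view(rng, small_universe)
        assert masked_kl(v.W, np.ones(len(small_universe)), v.W) == pytest.approx(0.0)

    def test_zero_mask_annihilates(self, rng):
        W = rng.uniform(size=(4, 4))
        A = rng.uniform(size=(4, 4))
        assert masked_kl(W, np.zeros(4), A) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            masked_kl(np.ones((3, 3)), np.ones(3), np.ones((4, 4)))

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            W = rng.uniform(size=(4, 4))
            A = rng.uniform(low=0.01, size=(4, 4))
            theta = (rng.uniform(size=4) < 0.7).astype(float)
            W[rng.uniform(size=(4, 4)) < 0.3] = 0.0
            assert masked_kl(W, theta, A) == pytest.approx(
                masked_kl_loop(W, theta, A), rel=1e-10
            )


class TestObjective:
    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            views, f = make_instance(rng)
            lam = rng.uniform(0, 5)
            assert objective(views, f, lam) == pytest.approx(
                objective_loop(views, f.H_c, f.H_s, lam), rel=1e-10
            )

    def test_planted_reconstruction_zero_lambda(self, rng, small_universe):
        # with A^(m) == W^(m) and lam=0 the objective reduces to
        # -sum_m sum theta theta (W log W - W)
        n = len(small_universe)
        f = make_random_factors(rng, n, 2, 2)
        views = tuple(
            raw_view(small_universe, f.reconstruction(m), np.ones(n))
            for m in range(2)
        )
        expected = -sum(
            np.sum(v.W * np.log(v.W) - v.W) for v in views
        )
        assert objective(views, f, lam=0.0) == pytest.approx(expected, rel=1e-10)

    def test_zero_factors_finite(self, rng, small_universe):
        n = len(small_universe)
        views = (
            make_random_view(rng, small_universe),
            make_random_view(rng, small_universe),
        )
        f = LatentFactors(np.zeros((n, 2)), (np.zeros((n, 2)), np.zeros((n, 2))))
        assert np.isfinite(objective(views, f, lam=1.0))


class TestUpdates:
    def test_shared_matches_loop_oracle(self, rng):
        for _ in range(10):
            views, f = make_instance(rng)
            lam = rng.uniform(0, 5)
            np.testing.assert_allclose(
                update_shared(views, f, lam),
                update_shared_loop(views, f.H_c, f.H_s, lam),
                rtol=1e-10,
            )

    @pytest.mark.parametrize("m", [0, 1])
    def test_specific_matches_loop_oracle(self, rng, m):
        for _ in range(10):
            views, f = make_instance(rng)
            lam = rng.uniform(0, 5)
            np.testing.assert_allclose(
                update_specific(views[m], f, m, lam),
                update_specific_loop(views[m], f.H_c, f.H_s, m, lam),
                rtol=1e-10,
            )

    def test_fixed_point_when_ratio_is_one(self, rng, small_universe):
        # W == A with full coverage and lam=0 makes the multiplicative
        # ratio exactly 1, so the damped update returns H_c unchanged.
        n = len(small_universe)
        f = make_random_factors(rng, n, 2, 0)
        A = f.reconstruction(0)
        views = tuple(raw_view(small_universe, A, np.ones(n)) for _ in range(2))
        np.testing.assert_allclose(update_shared(views, f, lam=0.0), f.H_c, rtol=1e-12)

    def test_zero_row_stays_zero(self, rng):
        views, f = make_instance(rng, coverage=1.0)
        f.H_c[2, :] = 0.0
        f.H_s[0][:, 1] = 0.0
        assert np.all(update_shared(views, f, lam=1.0)[2, :] == 0.0)
        assert np.all(update_specific(views[0], f, 0, lam=1.0)[:, 1] == 0.0)

    def test_nonnegativity_preserved(self, rng):
        for _ in range(20):
            views, f = make_instance(rng)
            assert np.all(update_shared(views, f, lam=0.3) >= 0)
            assert np.all(update_specific(views[0], f, 0, lam=0.3) >= 0)
            assert np.all(update_specific(views[1], f, 1, lam=0.3) >= 0)

    def test_mask_invariance_bitwise(self, rng):
        views, f = make_instance(rng, n=6, coverage=0.5)
        v = views[0]
        before_shared = update_shared(views, f, lam=1.0)
        before_spec = update_specific(v, f, 0, lam=1.0)
        before_J = objective(views, f, lam=1.0)
        W2 = v.W.copy()
        off = np.outer(v.theta, v.theta) == 0
        off &= ~np.eye(len(v.theta), dtype=bool)
        W2[off] = 42.0
        W2 = np.triu(W2, 1) + np.triu(W2, 1).T
        v2 = raw_view(v.universe, W2, v.theta)
        views2 = (v2, views[1])
        assert np.array_equal(update_shared(views2, f, lam=1.0), before_shared)
        assert np.array_equal(update_specific(v2, f, 0, lam=1.0), before_spec)
        assert objective(views2, f, lam=1.0) == before_J

    def test_degenerates_to_single_view_update(self, rng, small_universe):
        # eta = 1 (no specific block) with identical views: the two view
        # terms coincide, so the update equals the directly coded
        # single-view symmetric form with doubled numerator/denominator.
        n = len(small_universe)
        v = make_random_view(rng, small_universe, coverage=1.0)
        f = make_random_factors(rng, n, 3, 0)
        lam = 0.7
        got = update_shared((v, v), f, lam)
        H = f.H_c
        mask = np.outer(v.theta, v.theta)
        A = np.maximum(H @ H.T, 1e-12)
        num = 2 * ((mask * v.W) / A) @ H
        den = 2 * (mask @ H) + lam * H
        expected = H / 2 + 0.5 * H * num / np.maximum(den, 1e-12)
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestDiscretize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.9, 0.5, 0.45, 0.01], [1, 1, 1, 0]),
            ([1.0, 0.0, 0.0], [1, 0, 0]),
            # exact ties (binary-representable gaps) -> fewest assignments
            ([0.75, 0.5, 0.25, 0.0], [1, 0, 0, 0]),
            ([0.0, 0.0, 0.0], [0, 0, 0]),
        ],
    )
    def test_gap_rule_examples(self, row, expected):
        assert discretize(np.array([row])).tolist() == [expected]

    def test_matches_brute_force(self, rng):
        H = rng.uniform(size=(50, 6))
        H[rng.uniform(size=H.shape) < 0.3] = 0.0
        got = discretize(H)
        for i in range(H.shape[0]):
            assert got[i].tolist() == discretize_row_brute(H[i]).tolist()

    def test_constant_row_gets_single_assignment(self):
        out = discretize(np.array([[0.5, 0.5, 0.5]]))
        assert out.sum() == 3  # all entries >= threshold under all-zero gaps

    def test_never_assigns_all_columns_for_distinct_values(self, rng):
        H = rng.uniform(size=(40, 5))  # distinct values a.s.
        assert np.all(discretize(H).sum(axis=1) < 5)

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            discretize(np.ones((3, 1)))


class TestExtractComplexes:
    def test_size_filter_and_dedupe(self):
        uni = ProteinUniverse(["A", "B", "C", "D"])
        H = np.array(
            [[1, 1, 1], [1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8
        )
        cs = extract_complexes(H, uni, min_size=3)
        assert cs.member_sets == [frozenset({"A", "B", "C"})]
        cs2 = extract_complexes(H, uni, min_size=2)
        assert frozenset({"A", "D"}) in cs2.member_sets

    def test_duplicate_columns_collapse(self):
        uni = ProteinUniverse(["A", "B", "C"])
        H = np.ones((3, 2), dtype=np.int8)
        cs = extract_complexes(H, uni, min_size=3)
        assert len(cs) == 1
        assert cs.complexes[0][0] == "k0"


class TestFit:
    def make_views(self, seed, n=15, coverage=0.9):
        rng = np.random.default_rng(seed)
        uni = ProteinUniverse([f"P{i}" for i in range(n)])
        return (
            make_random_view(rng, uni, coverage=coverage),
            make_random_view(rng, uni, coverage=coverage),
        )

    def test_deterministic_under_seed(self):
        views = self.make_views(3)
        cfg = ModelConfig(K=6, lam=0.5, seed=11, n_restarts=3, max_iter=40)
        r1, r2 = fit(views, cfg), fit(views, cfg)
        assert np.array_equal(r1.restart_objectives, r2.restart_objectives)
        assert np.array_equal(r1.assignment, r2.assignment)
        assert list(r1.complexes) == list(r2.complexes)

    def test_trace_non_increasing(self):
        for seed in range(5):
            views = self.make_views(seed)
            cfg = ModelConfig(K=6, lam=1.0, seed=seed, n_restarts=2, max_iter=60)
            res = fit(views, cfg)
            t = res.objective_trace
            assert np.all(np.diff(t) <= MONOTONE_RTOL * np.abs(t[:-1]))

    def test_covered_proteins_assigned(self):
        views = self.make_views(7, coverage=1.0)
        cfg = ModelConfig(K=6, lam=0.5, seed=1, n_restarts=2, max_iter=60)
        res = fit(views, cfg)
        covered = (views[0].theta + views[1].theta) > 0
        assert np.all(res.assignment[covered].sum(axis=1) >= 1)
        assert res.unclustered == []

    def test_best_restart_is_minimizer(self):
        views = self.make_views(5)
        cfg = ModelConfig(K=6, lam=0.5, seed=2, n_restarts=4, max_iter=40)
        res = fit(views, cfg)
        assert res.objective_trace[-1] == np.nanmin(res.restart_objectives)
        assert res.best_restart == int(np.nanargmin(res.restart_objectives))

    def test_requires_aligned_views(self):
        v1, _ = self.make_views(1)
        v2, _ = self.make_views(2, n=10)
        with pytest.raises(ValueError, match="aligned"):
            fit((v1, v2), ModelConfig(K=4))


def test_trace_norm_identity(rng):
    # sum of singular values of HH' equals ||H||_F^2 for nonnegative H
    for _ in range(10):
        H = rng.uniform(size=(12, 4))
        A = H @ H.T
        sv = np.linalg.svd(A, compute_uv=False)
        assert sv.sum() == pytest.approx(np.sum(H**2), abs=1e-8)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(K=0)
    with pytest.raises(ValueError):
        ModelConfig(K=4, tol=0.0)
    with pytest.raises(ValueError):
        ModelConfig(K=4, eta=1.5)
    with pytest.raises(ValueError):
        ModelConfig(K=4, lam=-1.0)
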