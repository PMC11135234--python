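"""Unit and property tests for the multiplicative-update NMF core."""

import numpy as np
import pytest

import uiknmf as u
from uiknmf.nmf import EPS_DEFAULT, frobenius_objective, kl_objective


# ---------------------------------------------------------------------------
# independent straight-loop reference implementations (oracles)
# ---------------------------------------------------------------------------

def ref_update_frobenius(V, W, H, eps):
    """Elementwise-loop Lee-Seung Frobenius step: H first, then W."""
    m, n = V.shape
    r = W.shape[1]
    WH = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            WH[i, j] = sum(W[i, a] * H[a, j] for a in range(r))
    Hn = np.zeros_like(H)
    for a in range(r):
        for j in range(n):
            num = sum(W[i, a] * V[i, j] for i in range(m))
            den = sum(W[i, a] * WH[i, j] for i in range(m)) + eps
            Hn[a, j] = H[a, j] * num / den
    WHn = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            WHn[i, j] = sum(W[i, a] * Hn[a, j] for a in range(r))
    Wn = np.zeros_like(W)
    for i in range(m):
        for a in range(r):
            num = sum(V[i, j] * Hn[a, j] for j in range(n))
            den = sum(WHn[i, j] * Hn[a, j] for j in range(n)) + eps
            Wn[i, a] = W[i, a] * num / den
    return Wn, Hn


def ref_update_kl(V, W, H, eps):
    """Elementwise-loop KL-divergence step: H first, then W."""
    m, n = V.shape
    r = W.shape[1]
    WH = W @ H
    Hn = np.zeros_like(H)
    for a in range(r):
        for j in range(n):
            num = sum(W[i, a] * V[i, j] / (WH[i, j] + eps) for i in range(m))
            Hn[a, j] = H[a, j] * num / (sum(W[i, a] for i in range(m)) + eps)
    WHn = W @ Hn
    Wn = np.zeros_like(W)
    for i in range(m):
        for a in range(r):
            num = sum(V[i, j] / (WHn[i, j] + eps) * Hn[a, j] for j in range(n))
            Wn[i, a] = W[i, a] * num / (sum(Hn[a, j] for j in range(n)) + eps)
    return Wn, Hn


# ---------------------------------------------------------------------------
# init_random
# ---------------------------------------------------------------------------

class TestInitRandom:
    def test_contract(self):
        W, H = u.init_random(2, 2, 1, seed=7, scale=1.0)
        assert W.shape == (2, 1) and H.shape == (1, 2)
        for M in (W, H):
            assert (M > 0).all() and (M <= 1).all()

    def test_determinism_bitwise(self):
        a = u.init_random(5, 4, 2, seed=11, scale=3.0)
        b = u.init_random(5, 4, 2, seed=11, scale=3.0)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rank_too_large(self):
        with pytest.raises(u.RankError):
            u.init_random(3, 4, 5, seed=0)

    def test_nonpositive_scale(self):
        with pytest.raises(u.ArgumentError):
            u.init_random(3, 4, 2, seed=0, scale=0.0)


# ---------------------------------------------------------------------------
# single update steps
# ---------------------------------------------------------------------------

class TestUpdates:
    def test_frobenius_hand_example(self):
        # V=[[1]], W=[[1]], H=[[2]]: H' = 2*(1)/(2) = 1, W' = 1*(1)/(1) = 1
        W, H = u.update_frobenius(np.array([[1.0]]), np.array([[1.0]]), np.array([[2.0]]))
        assert H[0, 0] == pytest.approx(1.0, rel=1e-12)
        assert W[0, 0] == pytest.approx(1.0, rel=1e-12)
        assert frobenius_objective(np.array([[1.0]]), W, H) == pytest.approx(0.0, abs=1e-15)

    def test_kl_hand_example(self):
        # V=[[2]], W=[[1]], H=[[1]]: H' = 1*(2/1)/1 = 2
        W, H = u.update_kl(np.array([[2.0]]), np.array([[1.0]]), np.array([[1.0]]))
        assert H[0, 0] == pytest.approx(2.0, rel=1e-9)
        assert W[0, 0] == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("update", [u.update_frobenius, u.update_kl])
    def test_exact_product_is_fixed_point(self, update, rng):
        W = rng.uniform(0.5, 1.5, (6, 2))
        H = rng.uniform(0.5, 1.5, (2, 5))
        V = W @ H
        W2, H2 = update(V, W, H)
        assert np.allclose(W2, W, rtol=1e-9)
        assert np.allclose(H2, H, rtol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(u.DimensionError):
            u.update_frobenius(np.ones((3, 3)), np.ones((2, 2)), np.ones((2, 3)))
        with pytest.raises(u.DimensionError):
            u.update_kl(np.ones((3, 3)), np.ones((3, 2)), np.ones((2, 4)))

    @pytest.mark.parametrize(
        "update,ref,shape",
        [
            (u.update_frobenius, ref_update_frobenius, (5, 4)),
            (u.update_kl, ref_update_kl, (6, 5)),
        ],
    )
    def test_matches_straight_loop_reference(self, update, ref, shape, rng):
        """200 steps: each vectorized step agrees with the loop oracle to 1e-10."""
        m, n = shape
        V = rng.uniform(0.1, 2.0, (m, n))
        W, H = u.init_random(m, n, 2, seed=99, scale=1.0)
        prev_obj = np.inf
        for _ in range(200):
            Wr, Hr = ref(V, W, H, EPS_DEFAULT)
            W, H = update(V, W, H)
            assert np.allclose(W, Wr, rtol=1e-10, atol=1e-13)
            assert np.allclose(H, Hr, rtol=1e-10, atol=1e-13)
            obj = (
                frobenius_objective(V, W, H)
                if update is u.update_frobenius
                else kl_objective(V, W, H)
            )
            assert obj <= prev_obj * (1 + 1e-9)
            prev_obj = obj


# ---------------------------------------------------------------------------
# smoothing matrix
# ---------------------------------------------------------------------------

class TestSmoothingMatrix:
    def test_theta_zero_is_identity(self):
        assert np.array_equal(u.smoothing_matrix(3, 0.0), np.eye(3))

    def test_formula_values(self):
        assert np.allclose(u.smoothing_matrix(2, 1.0), [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)
        assert np.allclose(u.smoothing_matrix(2, 0.5), [[0.75, 0.25], [0.25, 0.75]], atol=1e-15)

    @pytest.mark.parametrize("r,theta", [(2, 0.3), (5, 0.8), (7, 1.0)])
    def test_doubly_stochastic_symmetric(self, r, theta):
        S = u.smoothing_matrix(r, theta)
        assert np.allclose(S, S.T)
        assert np.allclose(S.sum(axis=0), 1.0)
        assert np.allclose(S.sum(axis=1), 1.0)

    def test_theta_out_of_range(self):
        with pytest.raises(u.ArgumentError):
            u.smoothing_matrix(3, 1.5)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_rank1_exact(self):
        V = u.TargetMatrix(np.outer([1.0, 2.0], [3.0, 4.0]))
        f = u.fit(V, 1, u.AlgorithmSpec(name="lee", seed=1))
        assert f.rss < 1e-8

    @pytest.mark.parametrize("name", ["lee", "brunet", "nsnmf"])
    def test_nonnegative_factors(self, name, small_noisy):
        f = u.fit(small_noisy, 3, u.AlgorithmSpec(name=name, seed=2))
        assert f.W.min() >= 0 and f.H.min() >= 0

    def test_deterministic(self, small_noisy):
        spec = u.AlgorithmSpec(name="brunet", seed=9)
        assert u.fit(small_noisy, 2, spec).rss == u.fit(small_noisy, 2, spec).rss

    @pytest.mark.parametrize("name", ["lee", "brunet", "nsnmf"])
    def test_objective_trace_nonincreasing(self, name, small_noisy):
        f = u.fit(small_noisy, 3, u.AlgorithmSpec(name=name, seed=4))
        t = np.asarray(f.objective_trace)
        assert (t[1:] <= t[:-1] * (1 + 1e-9)).all()

    def test_invalid_inputs(self, small_noisy):
        with pytest.raises(u.RankError):
            u.fit(small_noisy, 100, u.AlgorithmSpec())
        with pytest.raises(u.ValidationError):
            u.fit(np.array([[1.0, -1.0], [1.0, 1.0]]), 1, u.AlgorithmSpec())
        with pytest.raises(u.ValidationError):
            u.fit(np.array([[1.0, np.nan], [1.0, 1.0]]), 1, u.AlgorithmSpec())

    def test_scale_equivariance_lee(self, small_noisy):
        c = 3.7
        spec = u.AlgorithmSpec(name="lee", seed=4)
        base = u.fit(small_noisy, 2, spec).rss
        scaled = u.fit(small_noisy.scaled(c), 2, spec).rss
        assert scaled == pytest.approx(c**2 * base, rel=1e-6)

    def test_exact_recovery_best_of_restarts(self):
        """A positive exact-rank product is recovered to a 1e-6 relative
        residual by the best of 10 restarts run to objective convergence."""
        V = u.make_lowrank_fixture(20, 15, 3, seed=17)
        spec = u.AlgorithmSpec(name="lee", seed=6, objective_tol=1e-12, max_iter=8000)
        best = u.best_fit(u.fit_restarts(V, 3, spec, n_run=10))
        assert best.rss < 1e-6 * float((V.values**2).sum())

    def test_nsnmf_theta_zero_close_to_brunet(self, small_noisy):
        a = u.fit(small_noisy, 2, u.AlgorithmSpec(name="nsnmf", theta=0.0, seed=5))
        b = u.fit(small_noisy, 2, u.AlgorithmSpec(name="brunet", seed=5))
        assert a.rss == pytest.approx(b.rss, rel=1e-6)

    def test_objective_tol_stopping_converges_tighter(self, lowrank3):
        loose = u.fit(lowrank3, 3, u.AlgorithmSpec(name="lee", seed=8))
        tight = u.fit(
            lowrank3, 3, u.AlgorithmSpec(name="lee", seed=8, objective_tol=1e-12, max_iter=8000)
        )
        assert tight.rss <= loose.rss

    def test_crosscheck_against_sklearn(self, lowrank3):
        """Independent oracle: sklearn's MU solver reaches a comparable optimum."""
        from sklearn.decomposition import NMF

        model = NMF(
            n_components=3, solver="mu", beta_loss="frobenius", init="random",
            random_state=0, max_iter=2000, tol=1e-10,
        )
        Wk = model.fit_transform(lowrank3.values)
        sk_rss = float(((lowrank3.values - Wk @ model.components_) ** 2).sum())
        ours = u.best_fit(u.fit_restarts(lowrank3, 3, u.AlgorithmSpec(name="lee", seed=0), 5))
        norm = float((lowrank3.values**2).sum())
        assert ours.rss / norm < 1e-5
        assert abs(ours.rss - sk_rss) / norm < 1e-5


# ---------------------------------------------------------------------------
# rss
# ---------------------------------------------------------------------------

class TestRss:
    def test_exact_product_zero(self, rng):
        W = rng.uniform(0.5, 1.5, (4, 2))
        H = rng.uniform(0.5, 1.5, (2, 3))
        F = u.Factorization(W, H, 2, u.AlgorithmSpec(), 0, [], 0.0)
        assert u.rss(W @ H, F) == 0.0

    def test_hand_sum(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        F = u.Factorization(np.zeros((2, 1)), np.zeros((1, 2)), 1, u.AlgorithmSpec(), 0, [], 0.0)
        assert u.rss(V, F) == 2.0

    def test_brute_force_oracle(self, rng):
        V = rng.uniform(0, 2, (7, 5))
        W = rng.uniform(0, 1, (7, 3))
        H = rng.uniform(0, 1, (3, 5))
        F = u.Factorization(W, H, 3, u.AlgorithmSpec(), 0, [], 0.0)
        WH = W @ H
        expected = sum(
            (V[i, j] - WH[i, j]) ** 2 for i in range(7) for j in range(5)
        )
        assert u.rss(V, F) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        F = u.Factorization(np.ones((3, 1)), np.ones((1, 2)), 1, u.AlgorithmSpec(), 0, [], 0.0)
        with pytest.raises(u.DimensionError):
            u.rss(np.ones((4, 2)), F)
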