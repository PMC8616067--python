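"""NMF factorization: VAF, order selection, normalization, phase matching."""
import numpy as np
import pytest

import emgcycle as e
from emgcycle.decomposition import OrderSelectionError


def _planted(seed=0, n=3, t=200, noise=0.0):
    """Synergy-structured planted factors: per-phase dominant muscles (as the
    generator plants), jittered per seed so restarts face varied instances."""
    rng = np.random.default_rng(seed)
    W0 = e.SynthConfig().planted_W[:, :n] * np.exp(0.2 * rng.standard_normal((4, n)))
    tau = np.arange(t) / t
    H0 = np.vstack(
        [np.exp(-0.5 * ((tau - c) / 0.08) ** 2) for c in (0.2, 0.5, 0.8)[:n]]
    )
    M = W0 @ H0
    if noise:
        M = np.clip(M + noise * M.mean() * rng.standard_normal(M.shape), 0, None)
    return M, W0, H0


class TestNmf:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 1.0, 5)
        h = rng.uniform(0.1, 1.0, 100)
        model = e.nmf(np.outer(w, h), 1, seed=0, restarts=5)
        assert model.vaf >= 0.9999

    def test_loss_non_increasing_every_restart(self):
        M, _, _ = _planted(seed=2, noise=0.05)
        model = e.nmf(M, 3, seed=3, restarts=5, max_iter=200)
        assert len(model.loss_curves) == 5
        for curve in model.loss_curves:
            assert np.all(np.diff(curve) <= 1e-9 * np.maximum(curve[:-1], 1e-30))

    def test_deterministic_given_seed(self):
        M, _, _ = _planted(seed=4, noise=0.05)
        a = e.nmf(M, 3, seed=9)
        b = e.nmf(M, 3, seed=9)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)

    def test_planted_recovery_with_noise(self):
        """W recovered (after matching) at mean r >= 0.95 over several seeds."""
        corrs = []
        for seed in range(5):
            M, W0, H0 = _planted(seed=seed, noise=0.01)
            model = e.nmf(M, 3, seed=seed, restarts=10)
            ref = e.SynergyModel(
                W=W0, H=H0, n_phases=3, vaf=1.0, converged=True, n_iter=0
            )
            matched = e.match_phases(model, ref)
            corrs.append(
                np.mean(
                    [np.corrcoef(matched.W[:, i], W0[:, i])[0, 1] for i in range(3)]
                )
            )
        assert np.mean(corrs) >= 0.95

    def test_nonnegativity_preserved(self):
        M, _, _ = _planted(seed=5, noise=0.1)
        model = e.nmf(M, 2, seed=1, restarts=3)
        assert np.all(model.W >= 0) and np.all(model.H >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            e.nmf(np.zeros((3, 10)), 2)
        M, _, _ = _planted()
        with pytest.raises(ValueError, match="order"):
            e.nmf(M, 5)
        with pytest.raises(ValueError, match="nonnegative"):
            e.nmf(-M, 2)

    def test_against_sklearn_reference(self):
        """Reconstruction error comparable to sklearn's NMF (independent
        implementation) on the same matrix and order."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        M, _, _ = _planted(seed=6, noise=0.02)
        ours = e.nmf(M, 3, seed=0, restarts=10)
        ref = sklearn.NMF(
            n_components=3, init="random", random_state=0, max_iter=2000, tol=1e-8
        )
        Wr = ref.fit_transform(M)
        err_ref = np.linalg.norm(M - Wr @ ref.components_) ** 2
        err_ours = np.linalg.norm(M - ours.reconstruction()) ** 2
        assert err_ours <= 1.05 * err_ref + 1e-12


class TestVaf:
    def test_exact_factorization_gives_one(self):
        M, W0, H0 = _planted(seed=7)
        assert e.vaf(M, W0, H0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_model_gives_zero(self):
        M, W0, H0 = _planted(seed=8)
        assert e.vaf(M, np.zeros_like(W0), np.zeros_like(H0)) == 0.0

    def test_constructed_residual_ratio(self):
        """M = WH + E with ||E||^2 = 0.04 ||M||^2 gives VAF 0.96."""
        rng = np.random.default_rng(9)
        W = rng.uniform(0.1, 1.0, (4, 2))
        H = rng.uniform(0.1, 1.0, (2, 50))
        R = W @ H
        E = rng.standard_normal(R.shape)
        # make the residual orthogonal to R so norms add exactly
        E -= R * (np.sum(E * R) / np.sum(R * R))
        M = R + E * np.sqrt(0.04 / 0.96) * np.linalg.norm(R) / np.linalg.norm(E)
        assert e.vaf(M, W, H) == pytest.approx(0.96, abs=1e-9)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            e.vaf(np.zeros((2, 5)), np.zeros((2, 1)), np.zeros((1, 5)))


class TestSelectOrder:
    def test_exact_rank_two(self):
        rng = np.random.default_rng(10)
        W0 = rng.uniform(0.1, 1.0, (4, 2))
        tau = np.arange(100) / 100
        H0 = np.vstack(
            [
                np.exp(-0.5 * ((tau - 0.25) / 0.1) ** 2),
                np.exp(-0.5 * ((tau - 0.75) / 0.1) ** 2),
            ]
        )
        M = W0 @ H0
        rank1 = e.nmf(M, 1, seed=0, restarts=10)
        assert rank1.vaf < 0.95  # rank-1 genuinely insufficient
        assert e.select_order(M, 0.95, 4, seed=0) == 2

    def test_threshold_zero_returns_one(self):
        M, _, _ = _planted(seed=11)
        assert e.select_order(M, 0.0, 4) == 1

    def test_unreachable_threshold_raises_with_best(self):
        rng = np.random.default_rng(12)
        M = rng.uniform(0.1, 1.0, (4, 50))  # full-rank noise
        with pytest.raises(OrderSelectionError) as exc:
            e.select_order(M, 0.999999999, 2, seed=0, restarts=2, max_iter=50)
        assert 1 <= exc.value.best_order <= 2
        assert exc.value.best_vaf < 1.0


class TestNormalizeAndMatch:
    def test_normalize_transfers_scale(self):
        M, W0, H0 = _planted(seed=13)
        model = e.nmf(M, 3, seed=0, restarts=3)
        normed = e.normalize_model(model)
        assert np.allclose(normed.H.max(axis=1), 1.0)
        assert np.max(np.abs(normed.reconstruction() - model.reconstruction())) < 1e-9
        again = e.normalize_model(normed)
        assert np.allclose(again.W, normed.W) and np.allclose(again.H, normed.H)

    def test_explicit_row_scale(self):
        W = np.ones((3, 1))
        H = np.array([[1.0, 2.5, 0.5]])
        model = e.SynergyModel(W=W, H=H, n_phases=1, vaf=1.0, converged=True, n_iter=0)
        normed = e.normalize_model(model)
        assert normed.H.max() == 1.0
        assert np.allclose(normed.W, 2.5)

    def test_zero_row_rejected(self):
        model = e.SynergyModel(
            W=np.ones((2, 1)), H=np.zeros((1, 5)), n_phases=1, vaf=0.0,
            converged=True, n_iter=0,
        )
        with pytest.raises(ValueError):
            e.normalize_model(model)

    def test_match_to_self_is_identity(self):
        M, _, _ = _planted(seed=14, noise=0.05)
        model = e.nmf(M, 3, seed=0, restarts=3)
        matched = e.match_phases(model, model)
        assert np.array_equal(matched.W, model.W)
        assert np.array_equal(matched.H, model.H)

    def test_swapped_reference_recovers_swap(self):
        M, _, _ = _planted(seed=15, noise=0.05)
        model = e.nmf(M, 3, seed=0, restarts=3)
        perm = [2, 0, 1]
        swapped = e.SynergyModel(
            W=model.W[:, perm], H=model.H[perm, :], n_phases=3, vaf=model.vaf,
            converged=True, n_iter=0,
        )
        matched = e.match_phases(swapped, model)
        assert np.allclose(matched.W, model.W)
        assert np.allclose(matched.H, model.H)

    def test_dimension_mismatch(self):
        M, _, _ = _planted(seed=16)
        a = e.nmf(M, 2, seed=0, restarts=2)
        b = e.nmf(M, 3, seed=0, restarts=2)
        with pytest.raises(ValueError):
            e.match_phases(a, b)


def test_vaf_non_decreasing_in_order():
    """Best-of-restarts VAF grows with model order (statistical property)."""
    violations = 0
    runs = 0
    for seed in range(5):
        M, _, _ = _planted(seed=seed, noise=0.05)
        vafs = [e.nmf(M, n, seed=seed, restarts=5).vaf for n in (1, 2, 3)]
        for lo, hi in zip(vafs, vafs[1:]):
            runs += 1
            violations += hi < lo - 1e-9
    assert violations / runs < 0.05
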