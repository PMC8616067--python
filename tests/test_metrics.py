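"""Relative phase contribution and inter-cycle stability indices."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgcycle as e
from emgcycle.metrics import DegenerateMetricError


def _direct_contribution(W, H):
    """Independent double-loop evaluation of the contribution formula."""
    n = W.shape[1]
    raw = []
    for i in range(n):
        acc = 0.0
        for m in range(W.shape[0]):
            acc += W[m, i] * H[i, :].sum()
        raw.append(acc)
    total = sum(raw)
    return np.array([r / total for r in raw])


class TestRelativeContribution:
    def test_single_phase_is_one(self):
        out = e.relative_contribution(np.ones((4, 1)), np.ones((1, 10)))
        assert np.allclose(out.C, [1.0])

    def test_hand_computed_example(self):
        # column sums [2, 1], row sums [3, 6] -> raw [6, 6] -> [0.5, 0.5]
        W = np.array([[1.0, 0.5], [1.0, 0.5]])
        H = np.vstack([np.full(3, 1.0), np.full(3, 2.0)])
        out = e.relative_contribution(W, H)
        assert np.allclose(out.C, [0.5, 0.5], atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_matches_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        m, n, t = rng.integers(2, 6), rng.integers(1, 5), rng.integers(3, 30)
        W = rng.uniform(0.0, 2.0, (m, n))
        H = rng.uniform(0.0, 2.0, (n, t))
        if (W.sum(axis=0) * H.sum(axis=1)).sum() == 0:
            return
        out = e.relative_contribution(W, H)
        assert np.allclose(out.C, _direct_contribution(W, H), atol=1e-9)
        assert out.C.sum() == pytest.approx(1.0, abs=1e-9)

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 1.0, (4, 3))
        H = rng.uniform(0.1, 1.0, (3, 20))
        a = e.relative_contribution(W, H).C
        b = e.relative_contribution(3.7 * W, 3.7 * H).C
        assert np.allclose(a, b, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1.0, (4, 3))
        H = rng.uniform(0.1, 1.0, (3, 20))
        perm = [2, 0, 1]
        a = e.relative_contribution(W, H).C[perm]
        b = e.relative_contribution(W[:, perm], H[perm, :]).C
        assert np.allclose(a, b, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            e.relative_contribution(np.zeros((3, 2)), np.zeros((2, 5)))


class TestStabilityIndices:
    def test_identical_traces_give_one(self):
        H_set = np.tile(np.array([0.1, 0.9, 0.4, 0.2]), (5, 1))
        assert e.temporal_stability(H_set) == pytest.approx(1.0)

    def test_anticorrelated_traces_give_minus_one(self):
        H_set = np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]])
        assert e.temporal_stability(H_set) == pytest.approx(-1.0)

    def test_spatial_identical_and_reversed(self):
        W_set = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (3, 1))
        assert e.spatial_stability(W_set) == pytest.approx(1.0)
        W_rev = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert e.spatial_stability(W_rev) == pytest.approx(-1.0)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        vals = [
            e.temporal_stability(rng.uniform(0, 1, (6, 50))) for _ in range(10)
        ]
        assert all(-1.0 <= v <= 1.0 for v in vals)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        H_set = rng.uniform(0, 1, (4, 30))
        assert e.temporal_stability(H_set) == pytest.approx(
            e.temporal_stability(10.0 * H_set)
        )

    def test_constant_pairs_skipped_then_degenerate(self):
        H_set = np.vstack([np.ones(10), np.ones(10)])
        with pytest.raises(DegenerateMetricError):
            e.temporal_stability(H_set)
        mixed = np.vstack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            val = e.temporal_stability(mixed)
        assert val == pytest.approx(1.0)

    def test_spatial_needs_three_muscles(self):
        with pytest.raises(ValueError, match="3 muscles"):
            e.spatial_stability(np.ones((3, 2)))

    def test_temporal_decreases_with_jitter(self):
        """Small grid version of the jitter-monotonicity property."""
        means = []
        for jitter in (0.0, 0.05):
            vals = []
            for seed in range(3):
                cfg = e.SynthConfig(seed=seed, timing_jitter_sd=jitter)
                session, _ = e.generate_trial(cfg)
                env = e.preprocess(session)
                b = e.detect_boundaries(e.composite_envelope(env), cfg.fs_hz)
                ncs = e.normalize_cycles(e.segment(env, b))
                ref = e.nmf(
                    ncs.tensor.transpose(1, 0, 2).reshape(cfg.n_muscles, -1),
                    3,
                    seed=seed,
                    restarts=5,
                )
                models = e.per_cycle_models(ncs, ref, seed=seed)
                vals.append(e.stability_from_models(models).temporal.mean())
            means.append(np.mean(vals))
        assert means[1] < means[0]


class TestPerCycleModels:
    def test_zero_jitter_recovery(self, clean_normalized):
        """Per-cycle W matches the planted weights at r >= 0.98."""
        from conftest import planted_reference

        cfg, truth, ncs = clean_normalized
        ref = planted_reference(truth, ncs.n_cycles)
        models = e.per_cycle_models(ncs, ref, seed=0)
        assert len(models) == ncs.n_cycles
        for cm in models:
            for i in range(3):
                r = np.corrcoef(cm.W[:, i], truth.true_W[:, i])[0, 1]
                assert r >= 0.98

    def test_matched_peak_order(self, clean_normalized):
        """After matching, per-cycle H rows peak in reference phase order."""
        from conftest import planted_reference

        cfg, truth, ncs = clean_normalized
        ref = planted_reference(truth, ncs.n_cycles)
        models = e.per_cycle_models(ncs, ref, seed=1)
        for cm in models:
            peaks = np.argmax(cm.H, axis=1)
            assert np.all(np.diff(peaks) > 0)

    def test_dropped_cycle_bookkeeping(self, clean_normalized):
        cfg, truth, ncs = clean_normalized
        import copy

        from conftest import planted_reference

        broken = copy.deepcopy(ncs)
        broken.tensor[2] = 0.0  # an all-zero cycle cannot be factorized
        ref = planted_reference(truth, broken.n_cycles)
        with pytest.warns(UserWarning, match="dropped"):
            models = e.per_cycle_models(broken, ref, seed=0)
        assert len(models) == ncs.n_cycles - 1
        assert e.stability_from_models(models).n_cycles == ncs.n_cycles - 1

    def test_projection_mode(self, clean_normalized):
        from conftest import planted_reference

        cfg, truth, ncs = clean_normalized
        ref = planted_reference(truth, ncs.n_cycles)
        models = e.per_cycle_models(ncs, ref, seed=0, mode="projection")
        for cm in models:
            assert np.array_equal(cm.W, ref.W)
            assert np.all(cm.H >= 0)
            assert cm.vaf > 0.9
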