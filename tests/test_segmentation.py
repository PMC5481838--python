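"""CER segmentation, smoothing, shared-width mixture fitting and scoring."""

import numpy as np
import pytest

from subdiff import segmentation as seg
from subdiff.trackio import Trajectory, TrajectoryEnsemble

from conftest import make_trajectory


def make_switching_ensemble(n_traj=80, T=600, sigmas=(10.0, 30.0, 100.0),
                            dwell=200, seed=0):
    """Trajectories switching between k Gaussian-step states (ground truth kept)."""
    rng = np.random.default_rng(seed)
    trajs, truth = [], []
    k = len(sigmas)
    for i in range(n_traj):
        state = int(rng.integers(0, k))
        states = np.empty(T, dtype=int)
        xy = np.zeros((T, 2))
        for t in range(T):
            if t > 0 and rng.random() < 1.0 / dwell:
                state = int((state + rng.integers(1, k)) % k)
            states[t] = state
            if t > 0:
                xy[t] = xy[t - 1] + rng.standard_normal(2) * sigmas[state]
        trajs.append(Trajectory(id=i, frames=np.arange(T), xy=xy))
        truth.append(states)
    return TrajectoryEnsemble(trajs, frame_interval=1.0), truth


def _rayleigh(rng, sigma, n):
    return np.hypot(rng.standard_normal(n) * sigma, rng.standard_normal(n) * sigma)


THREE_STATE_THRESHOLDS = seg.ThresholdSet([70.0, 150.0], [10, 5])


@pytest.fixture(scope="module")
def scan_results():
    ens, _ = make_switching_ensemble(n_traj=60, seed=3)
    sets = [seg.ThresholdSet([r, 150.0], [10, 5]) for r in (30.0, 70.0, 110.0)]
    return seg.scan_thresholds(ens, sets)


class TestCER:
    def test_stationary_track_all_slowest(self):
        t = make_trajectory(np.zeros((100, 2)))
        states = seg.cer_segment(t, THREE_STATE_THRESHOLDS).states
        w = max(THREE_STATE_THRESHOLDS.n_th)
        assert np.all(states[:-w] == 1)
        # trailing points with truncated, escape-free windows are undecidable
        assert np.all(states[-w:] == seg.UNASSIGNED)

    def test_ballistic_track_all_fastest(self):
        xy = np.stack([np.arange(100.0) * 200.0, np.zeros(100)], axis=1)
        states = seg.cer_segment(make_trajectory(xy), THREE_STATE_THRESHOLDS).states
        assert np.all(states[:-1] == 3)

    def test_two_regime_switch_detected(self):
        rng = np.random.default_rng(1)
        slow = np.cumsum(rng.standard_normal((200, 2)) * 5.0, axis=0)
        fast = slow[-1] + np.cumsum(rng.standard_normal((200, 2)) * 50.0, axis=0)
        t = make_trajectory(np.concatenate([slow, fast]))
        ts = seg.ThresholdSet([60.0], [8])
        states = seg.smooth_states(seg.cer_segment(t, ts)).states
        switch = np.argmax(states == 2)
        assert abs(int(switch) - 200) <= 8

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        xy = np.cumsum(rng.standard_normal((300, 2)) * 20.0, axis=0)
        ts = seg.ThresholdSet([60.0, 150.0], [10, 5])
        c = 7.3
        ts_scaled = seg.ThresholdSet([60.0 * c, 150.0 * c], [10, 5])
        a = seg.cer_segment(make_trajectory(xy), ts).states
        b = seg.cer_segment(make_trajectory(xy * c), ts_scaled).states
        assert np.array_equal(a, b)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            seg.cer_segment(make_trajectory(np.zeros((8, 2))), THREE_STATE_THRESHOLDS)


class TestSmoothing:
    def _seq(self, labels, k=3):
        return seg.StateSequence(track_id=0, states=np.array(labels), k=k)

    def test_worked_example_collapses(self):
        out = seg.smooth_states(self._seq([1, 1, 1, 2, 2, 1, 1, 1]))
        assert np.all(out.states == 1)

    def test_gap_of_four_unchanged(self):
        labels = [1, 1, 2, 2, 2, 2, 1, 1]
        out = seg.smooth_states(self._seq(labels))
        assert np.array_equal(out.states, labels)

    def test_alternating_resolved_and_idempotent(self):
        labels = [1, 2, 1, 2, 1, 2, 1]
        out = seg.smooth_states(self._seq(labels))
        again = seg.smooth_states(out)
        assert np.array_equal(out.states, again.states)

    def test_absorbs_unassigned_gaps(self):
        out = seg.smooth_states(self._seq([2, 2, 0, 0, 2, 2]))
        assert np.all(out.states == 2)


class TestExtract:
    def _traj(self, n=200):
        return make_trajectory(np.zeros((n, 2)))

    def test_single_state_single_segment(self):
        sq = seg.StateSequence(0, np.full(200, 2), 3)
        out = seg.extract_segments(self._traj(), sq)
        assert len(out) == 1 and len(out[0]) == 200 and out[0].state == 2

    def test_short_middle_run_discarded(self):
        states = np.concatenate([np.full(60, 1), np.full(30, 2), np.full(60, 1)])
        out = seg.extract_segments(self._traj(150), seg.StateSequence(0, states, 3))
        assert [s.state for s in out] == [1, 1]
        assert [len(s) for s in out] == [60, 60]

    def test_all_short_runs_give_nothing(self):
        states = np.tile(np.concatenate([np.full(20, 1), np.full(20, 2)]), 5)
        out = seg.extract_segments(self._traj(200), seg.StateSequence(0, states, 3))
        assert out == []


class TestStepDistribution:
    def test_mass_is_one(self, rng):
        edges, dens = seg.step_size_distribution(_rayleigh(rng, 20.0, 5000))
        assert (dens * np.diff(edges)).sum() == pytest.approx(1.0)

    def test_gaussian_walk_matches_sampling_distribution(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        sample = _rayleigh(rng, 20.0, 20000)
        # KS against the Rayleigh law with the generative scale
        stat, p = stats.kstest(sample, stats.rayleigh(scale=20.0).cdf)
        assert p > 0.01


class TestMixture:
    def test_two_population_zero_mixing_identity(self):
        rng = np.random.default_rng(5)
        pools = [_rayleigh(rng, 10.0, 30000), _rayleigh(rng, 40.0, 30000)]
        fit = seg.fit_shared_gaussian_mixture(pools)
        assert np.allclose(fit.weights, np.eye(2), atol=0.02)
        assert fit.sigmas == pytest.approx([10.0, 40.0], rel=0.05)

    def test_identical_distributions_score_minimal(self):
        rng = np.random.default_rng(6)
        same = _rayleigh(rng, 20.0, 30000)
        fit = seg.fit_shared_gaussian_mixture([same, same.copy()])
        assert fit.score <= 0.5  # no separation achievable

    def test_five_percent_contamination_recovered(self):
        rng = np.random.default_rng(7)
        sig = (10.0, 30.0, 100.0)
        pools = []
        for j in range(3):
            other = (j + 1) % 3
            pools.append(np.concatenate([
                _rayleigh(rng, sig[j], 38000), _rayleigh(rng, sig[other], 2000)]))
        fit = seg.fit_shared_gaussian_mixture(pools)
        off = fit.weights[~np.eye(3, dtype=bool)]
        assert np.all(np.diag(fit.weights) > 0.9)
        big_off = off[off > 0.02]         # the three injected contaminations
        assert len(big_off) == 3
        assert np.allclose(big_off, 0.05, atol=0.02)


class TestScore:
    def test_identity_matrix_maximum(self):
        assert seg.mixing_score(np.eye(3)) == pytest.approx(3.0)

    def test_worked_example_matrix(self):
        W = np.array([[0.95, 0.05, 0.0],
                      [0.03, 0.92, 0.05],
                      [0.0, 0.07, 0.93]])
        assert seg.mixing_score(W) == pytest.approx(2.60, abs=1e-9)

    def test_uniform_matrix(self):
        assert seg.mixing_score(np.full((3, 3), 1 / 3)) == pytest.approx(-1.0)

    def test_malformed_rows_rejected(self):
        with pytest.raises(ValueError):
            seg.mixing_score(np.full((3, 3), 0.5))


class TestScanAndSelect:
    def test_single_set_grid(self):
        ens, _ = make_switching_ensemble(n_traj=20, seed=4)
        res = seg.scan_thresholds(ens, [THREE_STATE_THRESHOLDS])
        assert len(res) == 1 and res[0].valid

    def test_scores_bounded_by_k(self, scan_results):
        for r in scan_results:
            if r.valid:
                assert r.fit.score <= 3.0 + 1e-9

    def test_best_set_in_separation_band(self, scan_results):
        # generative scales 10/30/100: R=70 separates cleanly, 30 and 110 less so
        valid = [r for r in scan_results if r.valid]
        best = max(valid, key=lambda r: r.fit.score)
        assert best.thresholds.R_th[0] == 70.0

    def test_guideline_filters(self, scan_results):
        def result(Rth, diag, counts, pinned=False):
            k = 3
            W = np.zeros((k, k))
            np.fill_diagonal(W, diag)
            W[1, 0] = W[0, 1] = W[1, 2] = 1 - diag  # columns sum to 1
            fit = seg.MixtureFit(weights=W, sigmas=np.array([1.0, 3.0, 10.0]),
                                 score=seg.mixing_score(W), n_steps=np.array(counts),
                                 n_segments=np.array(counts), converged=True,
                                 pinned=pinned, kernel="rayleigh", residual=0.0)
            return seg.ScanResult(seg.ThresholdSet(Rth, [10, 5]), valid=True,
                                  fit=fit, meta={"n_segments": np.array(counts)})

        results = [result([30.0, 150.0], 0.95, [50, 50, 50]),   # R_th too small
                   result([70.0, 150.0], 0.95, [50, 50, 50]),   # accepted
                   result([70.0, 150.0], 0.80, [50, 50, 50]),   # mixed diagonal
                   result([70.0, 150.0], 1.00, [50, 50, 50], pinned=True),
                   result([70.0, 150.0], 0.95, [50, 2, 50])]    # starved state
        accepted, failures = seg.select_threshold_sets(results, 40.0, 0.9, 5)
        assert len(accepted) == 1
        assert accepted[0].thresholds.R_th == (70.0, 150.0)
        assert failures == {"invalid": 0, "R_th": 1, "diagonal": 2, "counts": 1}
        # relaxing every guideline accepts every valid set
        all_sets, _ = seg.select_threshold_sets(scan_results, 0.0, -1.0, 0)
        assert len(all_sets) == sum(r.valid and not r.fit.pinned for r in scan_results)

    def test_pinned_sets_rejected(self):
        rng = np.random.default_rng(9)
        pools = [_rayleigh(rng, 10.0, 20000), _rayleigh(rng, 60.0, 20000)]
        fit = seg.fit_shared_gaussian_mixture(pools)
        res = seg.ScanResult(seg.ThresholdSet([50.0], [8]), valid=True, fit=fit,
                             meta={"n_segments": np.array([50, 50])})
        if fit.pinned:
            accepted, failures = seg.select_threshold_sets([res], 40.0, 0.9, 5)
            assert accepted == [] and failures["diagonal"] == 1

    def test_pipeline_determinism(self):
        ens, _ = make_switching_ensemble(n_traj=20, seed=10)
        a = seg.scan_thresholds(ens, [THREE_STATE_THRESHOLDS])[0]
        b = seg.scan_thresholds(ens, [THREE_STATE_THRESHOLDS])[0]
        assert np.array_equal(a.fit.weights, b.fit.weights)
        assert a.fit.score == b.fit.score


class TestEndToEndRecovery:
    def test_three_state_recovery_with_purity(self):
        ens, truth = make_switching_ensemble(n_traj=80, seed=0)
        segs = seg.segment_ensemble(ens, THREE_STATE_THRESHOLDS)
        assert len(segs) > 100
        # segments match the generative state for the vast majority of frames
        purity = np.mean([
            np.mean(truth[s.parent_id][s.start:s.stop - 1] == s.state - 1)
            for s in segs])
        assert purity > 0.95
        pools = seg.pooled_steps_by_state(segs, 3)
        fit = seg.fit_shared_gaussian_mixture(pools)
        assert np.all(np.diag(fit.weights) >= 0.95)
        assert fit.sigmas == pytest.approx([10.0, 30.0, 100.0], rel=0.1)
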