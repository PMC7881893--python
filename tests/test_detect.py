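import numpy as np
import pytest

from saccadekit.detect import (
    DetectorConfig,
    EstimatorSpec,
    MAD_NORMAL_CONSTANT,
    PRESETS,
    detect_saccades,
    estimate_center_spread,
    excise_flanks,
    excision_count,
    find_peak_blocks,
    fixed_threshold_detect,
    iterate_peak_threshold,
    preset,
    refine_onset,
    refine_offset,
)
from saccadekit.types import GazeRecording
from saccadekit.velocity import savgol_velocity

from _oracles import (
    oracle_blocks,
    oracle_iterate,
    oracle_median_mad,
    oracle_offset,
    oracle_onset,
)

CLASSICAL = EstimatorSpec(kind="classical")
ROBUST = EstimatorSpec(kind="robust")


def fixture_speed(seed, n=400, integer=True):
    """Small synthetic speed trace: integer fixation noise plus pulses."""
    rng = np.random.default_rng(seed)
    speed = rng.integers(0, 21, size=n).astype(float)
    for _ in range(rng.integers(1, 4)):
        start = int(rng.integers(0, n - 30))
        width = int(rng.integers(6, 25))
        speed[start : start + width] = float(rng.integers(200, 600))
    return speed


class TestEstimator:
    def test_constant_samples(self):
        x = np.array([7.0, 7.0, 7.0, 7.0])
        assert estimate_center_spread(x, CLASSICAL) == (7.0, 0.0)
        assert estimate_center_spread(x, ROBUST) == (7.0, 0.0)

    def test_robust_against_sort_based_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
        center, spread = estimate_center_spread(x, ROBUST)
        o_center, o_spread = oracle_median_mad(list(x))
        assert center == o_center == 3.5
        assert spread == pytest.approx(o_spread)
        assert spread == pytest.approx(MAD_NORMAL_CONSTANT * 1.5)

    def test_breakdown_single_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 101)
        corrupted = x.copy()
        corrupted[np.argmax(corrupted)] = 1e6
        rc, rs = estimate_center_spread(x, ROBUST)
        rc2, rs2 = estimate_center_spread(corrupted, ROBUST)
        assert rc2 == rc and rs2 == pytest.approx(rs)
        _, cs = estimate_center_spread(x, CLASSICAL)
        _, cs2 = estimate_center_spread(corrupted, CLASSICAL)
        assert cs2 > 100 * cs

    def test_agreement_on_clean_gaussian(self):
        """Without outliers, classical and robust estimates agree within
        sampling error shrinking as 1/sqrt(n)."""
        rng = np.random.default_rng(2)
        for n in (500, 5000, 50000):
            x = rng.normal(30.0, 4.0, n)
            cc, cs = estimate_center_spread(x, CLASSICAL)
            rc, rs = estimate_center_spread(x, ROBUST)
            bound = 5.0 * 4.0 / np.sqrt(n)
            assert abs(cc - rc) < bound
            assert abs(cs - rs) < 2 * bound

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_center_spread(np.array([]), CLASSICAL)

    def test_estimator_spec_validation(self):
        with pytest.raises(ValueError):
            EstimatorSpec(kind="average")
        with pytest.raises(ValueError):
            EstimatorSpec(b_mode="normal_constant", b_value=2.0)


class TestExcision:
    def test_sample_counts_by_rate(self):
        assert excision_count(500) == 3
        assert excision_count(300) == 2
        assert excision_count(150) == 1

    def test_trims_both_flanks(self):
        assert excise_flanks([(0, 20)], fs=500) == [(3, 17)]

    def test_short_interval_dropped(self):
        assert excise_flanks([(10, 15)], fs=500) == []


class TestIteration:
    def test_constant_trace_converges_to_its_value(self):
        speed = np.full(1000, 10.0)
        cfg = DetectorConfig(estimator=CLASSICAL, lam=6.0, theta_init=200.0)
        res = iterate_peak_threshold(speed, cfg, fs=500)
        assert res.theta_pt == pytest.approx(10.0)
        assert res.center == pytest.approx(10.0) and res.spread == 0.0
        assert res.degenerate  # following iteration sees an empty x < 10 set
        assert not res.converged

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_bruteforce_oracle(self, seed):
        """The iteration agrees step-for-step with a literal
        re-implementation, for both estimators with and without excision."""
        rng = np.random.default_rng(seed + 1000)
        speed = fixture_speed(seed)
        robust = bool(seed % 2)
        excise = bool((seed // 2) % 2)
        lam = float(rng.integers(4, 11))
        theta_init = float(rng.integers(100, 301))
        cfg = DetectorConfig(
            estimator=ROBUST if robust else CLASSICAL,
            lam=lam,
            theta_init=theta_init,
            excise=excise,
        )
        res = iterate_peak_threshold(speed, cfg, fs=500)
        exp = oracle_iterate(
            speed,
            theta_init,
            lam,
            cfg.convergence_tol,
            cfg.max_iter,
            robust,
            excise=excise,
            k_excise=excision_count(500, cfg.min_fixation_dur),
        )
        assert res.iterations == exp["iterations"]
        assert res.converged == exp["converged"]
        assert res.degenerate == exp["degenerate"]
        np.testing.assert_allclose(res.theta_history, exp["history"], rtol=1e-12)
        np.testing.assert_allclose(res.theta_pt, exp["theta_pt"], rtol=1e-12)
        np.testing.assert_allclose(res.theta_onset, exp["theta_onset"], rtol=1e-12)

    def test_onset_threshold_below_peak_threshold(self):
        """theta_PT > theta_STonset whenever spread > 0 and lambda > 3."""
        for seed in range(10):
            speed = fixture_speed(seed + 77)
            for est in (CLASSICAL, ROBUST):
                cfg = DetectorConfig(estimator=est, lam=6.0)
                res = iterate_peak_threshold(speed, cfg, fs=500)
                if res.spread > 0:
                    assert res.theta_pt > res.theta_onset

    def test_iteration_cap(self):
        speed = fixture_speed(5)
        cfg = DetectorConfig(estimator=CLASSICAL, lam=6.0, max_iter=2)
        res = iterate_peak_threshold(speed, cfg, fs=500)
        assert res.iterations <= 2


class TestBlocks:
    def test_all_below_threshold(self):
        assert find_peak_blocks(np.zeros(100), 55.0, 0.010, 500) == []

    def test_single_block_above_min_duration(self):
        speed = np.zeros(100)
        speed[40:52] = 300.0  # 12 samples = 24 ms at 500 Hz
        assert find_peak_blocks(speed, 55.0, 0.010, 500) == [(40, 52)]

    def test_adjacent_runs_not_merged(self):
        speed = np.zeros(100)
        speed[20:30] = 300.0
        speed[30] = 10.0
        speed[31:41] = 300.0
        assert find_peak_blocks(speed, 55.0, 0.010, 500) == [(20, 30), (31, 41)]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_runlength_oracle(self, seed):
        speed = fixture_speed(seed + 300)
        theta = float(np.random.default_rng(seed).integers(30, 250))
        got = find_peak_blocks(speed, theta, 0.010, 500)
        assert got == oracle_blocks(list(speed), theta, 5)


class TestRefinement:
    def test_onset_at_local_minimum_before_rise(self):
        speed = np.concatenate(
            [np.full(20, 8.0), np.array([6.0, 4.0, 7.0, 30.0, 80.0, 200.0]),
             np.full(10, 300.0)]
        )
        onset, flagged = refine_onset(speed, (24, 36), theta_onset=20.0)
        o_onset, o_flag = oracle_onset(list(speed), 24, 20.0)
        assert (onset, flagged) == (o_onset, o_flag)
        assert speed[onset] == 4.0  # the local minimum preceding the rise

    def test_onset_at_trace_start_flagged(self):
        speed = np.full(30, 100.0)
        onset, flagged = refine_onset(speed, (0, 10), theta_onset=50.0)
        assert onset == 0 and flagged

    def test_symmetric_pulse_mirrors_onset_offset(self):
        """With equal onset/offset thresholds, a symmetric pulse refines
        to mirror-image boundaries."""
        up = np.linspace(0, 300, 16)
        speed = np.concatenate([np.zeros(30), up, up[::-1][1:], np.zeros(30)])
        blocks = find_peak_blocks(speed, 100.0, 0.010, 500)
        assert len(blocks) == 1
        onset, _ = refine_onset(speed, blocks[0], 20.0)
        offset, _ = oracle_offset(list(speed), blocks[0][1], 20.0)
        mid = 30 + 15  # apex index
        assert (mid - onset) == (offset - mid)

    @pytest.mark.parametrize("seed", range(40))
    def test_offset_matches_forward_scan_oracle(self, seed):
        rng = np.random.default_rng(seed + 900)
        speed = fixture_speed(seed + 900)
        blocks = find_peak_blocks(speed, 150.0, 0.010, 500)
        if not blocks:
            pytest.skip("fixture produced no blocks")
        cfg = DetectorConfig(estimator=CLASSICAL, lam=6.0)
        thr = iterate_peak_threshold(speed, cfg, fs=500)
        for blk in blocks:
            onset, _ = refine_onset(speed, blk, thr.theta_onset)
            o_onset, _ = oracle_onset(list(speed), blk[0], thr.theta_onset)
            assert onset == o_onset
            offset, _ = refine_offset(speed, blk, thr, cfg, 500, onset)
            # oracle recomputes the mixed offset threshold independently
            w = int(round(cfg.local_noise_window * 500))
            seg = speed[max(0, onset - w) : onset]
            if seg.size == 0:
                theta_off = thr.theta_onset  # no pre-saccadic window available
            else:
                m = float(np.mean(seg))
                s = float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0
                theta_off = 0.7 * thr.theta_onset + 0.3 * (m + 3.0 * s)
            o_offset, _ = oracle_offset(list(speed), blk[1], theta_off)
            assert offset == o_offset

    def test_local_noise_window_constant_speed(self):
        """A constant 5 deg/s window has LocalNoise = 5 (zero SD)."""
        from saccadekit.detect import local_noise_level

        speed = np.concatenate([np.full(40, 5.0), np.full(20, 300.0)])
        value, flagged = local_noise_level(speed, 40, 0.040, 500, CLASSICAL)
        assert value == pytest.approx(5.0)
        assert not flagged


class TestDetectSaccades:
    def test_noise_free_recall_is_perfect(self, noisefree_scanpath):
        cfg, clean, noisy, gt = noisefree_scanpath
        from saccadekit.evaluate import match_events

        for name in PRESETS:
            events, thr = detect_saccades(noisy, preset(name, lam=6.0))
            m = match_events(gt, events)
            assert m.recall == 1.0, name

    def test_flat_recording_no_events(self):
        n = 500
        rec = GazeRecording(
            t=np.arange(n) / 500.0, x=np.zeros(n), y=np.zeros(n), fs=500.0
        )
        events, thr = detect_saccades(rec, preset("AT"))
        assert events == []

    def test_robust_threshold_not_above_classical(self, moderate_noise_scanpath):
        _, _, noisy, _ = moderate_noise_scanpath
        vel = savgol_velocity(noisy)
        _, thr_at = detect_saccades(noisy, preset("AT", lam=6.0), velocity=vel)
        _, thr_mad = detect_saccades(noisy, preset("AT-MAD", lam=6.0), velocity=vel)
        assert thr_mad.theta_pt <= thr_at.theta_pt

    def test_detection_is_deterministic(self, moderate_noise_scanpath):
        _, _, noisy, _ = moderate_noise_scanpath
        e1, t1 = detect_saccades(noisy, preset("AT-MAD"))
        e2, t2 = detect_saccades(noisy, preset("AT-MAD"))
        assert [(e.onset_idx, e.offset_idx) for e in e1] == [
            (e.onset_idx, e.offset_idx) for e in e2
        ]
        assert t1.theta_history == t2.theta_history

    def test_events_disjoint_and_ordered(self, moderate_noise_scanpath):
        _, _, noisy, _ = moderate_noise_scanpath
        events, _ = detect_saccades(noisy, preset("AT", lam=5.0))
        for a, b in zip(events, events[1:]):
            assert a.offset_idx <= b.onset_idx

    def test_corruption_moves_robust_threshold_less(self):
        """Corrupting a minority of samples shifts the robust converged
        threshold less than the classical one (breakdown robustness)."""
        rng = np.random.default_rng(8)
        speed = np.abs(rng.normal(10, 2, 2000))
        corrupted = speed.copy()
        idx = rng.choice(2000, size=600, replace=False)  # 30% < 50%
        corrupted[idx] = 90.0  # below theta_init, so the outliers can mask
        shifts = {}
        for name, est in (("classical", CLASSICAL), ("robust", ROBUST)):
            cfg = DetectorConfig(estimator=est, lam=6.0)
            t_clean = iterate_peak_threshold(speed, cfg, fs=500).theta_pt
            t_bad = iterate_peak_threshold(corrupted, cfg, fs=500).theta_pt
            shifts[name] = abs(t_bad - t_clean)
        assert shifts["robust"] < shifts["classical"]


class TestFixedThreshold:
    def test_flat_trace(self):
        n = 400
        rec = GazeRecording(
            t=np.arange(n) / 500.0, x=np.zeros(n), y=np.zeros(n), fs=500.0
        )
        assert fixed_threshold_detect(rec) == []

    def test_subthreshold_pulse_not_detected(self):
        """A pulse peaking at 50 deg/s stays below the 55 deg/s default."""
        n = 600
        fs = 500.0
        t = np.arange(n) / fs
        x = np.zeros(n)
        # 50 deg/s ramp over 40 ms
        x[300:321] = np.linspace(0, 50 * 0.040, 21)
        x[321:] = x[320]
        rec = GazeRecording(t=t, x=x, y=np.zeros(n), fs=fs)
        assert fixed_threshold_detect(rec) == []
        # but it is detected once the peak threshold drops below the peak
        assert len(fixed_threshold_detect(rec, theta_pt=30.0, theta_st=20.0)) == 1

    def test_threshold_ordering_enforced(self, noisefree_scanpath):
        _, _, noisy, _ = noisefree_scanpath
        with pytest.raises(ValueError):
            fixed_threshold_detect(noisy, theta_pt=45.0, theta_st=55.0)

    def test_detects_simulated_saccades(self, noisefree_scanpath):
        cfg, _, noisy, gt = noisefree_scanpath
        from saccadekit.evaluate import match_events

        events = fixed_threshold_detect(noisy)
        m = match_events(gt, events)
        assert m.recall == 1.0


class TestConfig:
    def test_json_roundtrip(self):
        cfg = preset("AT-MAD-excise", lam=7.5)
        assert DetectorConfig.from_json(cfg.to_json()) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            DetectorConfig.from_json('{"lam": 6.0, "bogus": 1}')

    def test_presets(self):
        assert preset("AT").estimator.kind == "classical"
        assert preset("AT-MAD").estimator.kind == "robust"
        assert preset("AT-MAD").lam == 9.0 and preset("AT").lam == 6.0
        assert preset("AT-excise").excise and preset("AT-MAD-excise").excise
        with pytest.raises(KeyError):
            preset("nope")
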