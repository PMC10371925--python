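import numpy as np
import pytest

from mgsaccade import (
    EmptyRunError,
    GazeRun,
    PreprocConfig,
    SamplingError,
    SimulationParams,
    TaskDesign,
    detect_blinks,
    detect_saccades,
    drift_correct,
    recalibrate_run,
    smooth_and_velocity,
)
from mgsaccade.preprocess import epochs_from_trials, preprocess_run, _valid_segments
from mgsaccade.pipeline import simulate_subject
from mgsaccade.simulate import _TraceBuilder

CFG = PreprocConfig()


def run_of(pupil, x=None, y=None):
    n = len(pupil)
    z = np.zeros(n)
    return GazeRun(0, np.arange(n, dtype=np.int64),
                   z if x is None else np.asarray(x, float),
                   z if y is None else np.asarray(y, float),
                   np.asarray(pupil, float))


class TestBlinks:
    def test_constant_pupil_no_blinks(self):
        intervals, valid = detect_blinks(run_of(np.full(5000, 1000.0)), CFG)
        assert intervals == [] and valid.all()

    def test_single_dropout_padded(self):
        pupil = np.full(10_000, 1000.0)
        pupil[5000:5041] = 0.0
        intervals, valid = detect_blinks(run_of(pupil), CFG)
        assert intervals == [(4800, 5240)]
        assert not valid[4800:5241].any() and valid[:4800].all() and valid[5241:].all()

    def test_dropout_at_start_clipped(self):
        pupil = np.full(5000, 1000.0)
        pupil[0:30] = 0.0
        intervals, _ = detect_blinks(run_of(pupil), CFG)
        assert intervals[0][0] == 0

    def test_padding_invariant_exhaustive(self):
        """Validity equals brute-force dilation of the sub-percentile mask."""
        rng = np.random.default_rng(0)
        pupil = 1000.0 + 40 * np.sin(np.arange(20_000) / 900.0) + rng.normal(0, 3, 20_000)
        for s in (3000, 9000, 15500):
            pupil[s : s + rng.integers(60, 120)] = 0.0
        _, valid = detect_blinks(run_of(pupil), CFG)
        q = np.quantile(pupil, 0.015)
        sub = np.flatnonzero(pupil < q)
        brute = np.ones_like(valid)
        for i in sub:
            brute[max(0, i - 200) : i + 201] = False
        assert np.array_equal(valid, brute)

    def test_all_invalid_raises(self):
        # sub-percentile dip at the center of a short run -> padding covers all
        pupil = np.abs(np.arange(300.0) - 150.0) + 500.0
        with pytest.raises(EmptyRunError):
            detect_blinks(run_of(pupil), CFG)


class TestSmoothVelocity:
    def test_constant_position_zero_speed(self):
        run = run_of(np.full(2000, 1000.0), x=np.ones(2000), y=np.ones(2000))
        _, _, speed = smooth_and_velocity(run, np.ones(2000, bool), CFG)
        assert np.allclose(speed, 0.0, atol=1e-12)

    def test_linear_ramp_speed(self):
        """A 0.05 deg/ms ramp reads 50 deg/s away from segment edges."""
        n = 3000
        x = 0.05 * np.arange(n)
        run = run_of(np.full(n, 1000.0), x=x)
        _, _, speed = smooth_and_velocity(run, np.ones(n, bool), CFG)
        assert np.allclose(speed[50:-50], 50.0, atol=1e-6)

    def test_isotropy(self):
        n = 3000
        ramp = 0.02 * np.arange(n)
        rx = run_of(np.full(n, 1000.0), x=ramp)
        ry = run_of(np.full(n, 1000.0), y=ramp)
        _, _, sx = smooth_and_velocity(rx, np.ones(n, bool), CFG)
        _, _, sy = smooth_and_velocity(ry, np.ones(n, bool), CFG)
        assert np.allclose(sx, sy, atol=1e-12)

    def test_nonuniform_sampling_rejected(self):
        run = run_of(np.full(100, 1000.0))
        run.t_ms = run.t_ms.copy()
        run.t_ms[50:] += 3
        with pytest.raises(SamplingError):
            smooth_and_velocity(run, np.ones(100, bool), CFG)


def _trace_with_saccades(saccade_specs, n=20_000):
    """Noise-free trace from the simulator's kinematic primitive."""
    params = SimulationParams()
    b = _TraceBuilder(n, params)
    for onset, to_xy in saccade_specs:
        b.saccade(onset, np.asarray(to_xy, float))
    pos = b.finish()
    return run_of(np.full(n, 1000.0), x=pos[:, 0], y=pos[:, 1]), b.log


class TestSaccadeDetection:
    def detect(self, run):
        valid = np.ones(run.n_samples, bool)
        xs, ys, speed = smooth_and_velocity(run, valid, CFG)
        return detect_saccades(run, xs, ys, speed, valid, CFG), xs, ys

    def test_injected_saccade_recovered(self):
        """An 8-deg movement yields exactly one saccade at the right time/size."""
        run, log = _trace_with_saccades([(5000, (8.0, 0.0))])
        events, _, _ = self.detect(run)
        assert len(events.saccades) == 1
        s = events.saccades[0]
        assert abs(s.onset_ms - log[0]["onset_ms"]) <= 2
        assert s.amplitude_deg == pytest.approx(8.0, abs=0.1)

    def test_amplitude_gate(self):
        """A 0.2-deg displacement stays below the 0.25-deg amplitude gate."""
        run, _ = _trace_with_saccades([(5000, (0.2, 0.0))])
        events, _, _ = self.detect(run)
        assert events.saccades == []

    def test_duration_gate(self):
        """A 5-ms supra-threshold speed burst fails the 7.5-ms duration gate."""
        n = 10_000
        run = run_of(np.full(n, 1000.0))
        x = np.zeros(n)
        x[5000:5005] = np.linspace(0.1, 0.5, 5)
        x[5005:] = 0.5
        speed = np.zeros(n)
        speed[5000:5005] = 100.0  # burst shorter than 0.0075 s
        events = detect_saccades(run, x, np.zeros(n), speed, np.ones(n, bool), CFG)
        assert events.saccades == []

    def test_no_false_alarms_on_fixation_jitter(self):
        rng = np.random.default_rng(6)
        n = 30_000
        run = run_of(
            np.full(n, 1000.0),
            x=rng.normal(0, 0.05, n),
            y=rng.normal(0, 0.05, n),
        )
        events, _, _ = self.detect(run)
        assert events.saccades == []

    def test_segmentation_tiles_valid_time(self, quiet_subject):
        """Saccades and fixations partition each valid segment exactly."""
        proc = quiet_subject["proc"]
        covered = np.zeros(len(proc.t_ms), dtype=int)
        for s in proc.events.saccades:
            covered[s.i_on : s.i_off + 1] += 1
        for f in proc.events.fixations:
            covered[f.i_start : f.i_end + 1] += 1
        assert np.all(covered[proc.valid] == 1)
        assert np.all(covered[~proc.valid] == 0)


class TestDriftCorrection:
    def test_offset_round_trip(self, one_run_design, quiet_params):
        """An injected constant offset is removed; endpoints shift with it."""
        import dataclasses
        trials, _, runs, _ = simulate_subject(one_run_design, quiet_params, seed=21)
        run = runs[0]
        epochs = epochs_from_trials(trials)
        shifted = run.copy()
        shifted.x += 0.8
        shifted.y += -0.5
        proc = preprocess_run(shifted, epochs)
        tr = trials[0]
        pre = slice(tr.t_start, tr.cue_onset)
        assert abs(np.median(proc.x[pre])) < 1e-6
        assert abs(np.median(proc.y[pre])) < 1e-6
        assert proc.drift_offsets[tr.trial_id] == pytest.approx((0.8, -0.5), abs=1e-9)

    def test_idempotence(self, quiet_subject, one_run_design):
        proc = quiet_subject["proc"]
        epochs = epochs_from_trials(quiet_subject["trials"])
        x0, y0 = proc.x.copy(), proc.y.copy()
        drift_correct(proc, epochs)
        assert np.allclose(proc.x, x0, atol=1e-9)
        assert np.allclose(proc.y, y0, atol=1e-9)

    def test_centered_trial_unchanged(self, one_run_design, quiet_params):
        trials, _, runs, _ = simulate_subject(one_run_design, quiet_params, seed=22)
        epochs = epochs_from_trials(trials)
        proc = preprocess_run(runs[0], epochs)
        # noise-free pre-cue gaze sits at the origin, so offsets are ~0
        offs = np.array(list(proc.drift_offsets.values()))
        assert np.allclose(offs, 0.0, atol=1e-9)


WARP = ((0.15, 1.03, 0.0008, -0.00012), (-0.1, 0.98, -0.0006, 0.00009))


def _toy_session(n_trials=10, seed=0):
    """Trials whose feedback fixations sit exactly on the true targets."""
    from conftest import make_toy_proc, make_trial

    rng = np.random.default_rng(seed)
    angles = rng.uniform(0, 360, n_trials)
    trials, saccades = [], []
    step = 9800
    for i, ang in enumerate(angles):
        t0 = i * step
        tr = make_trial("R1", angles=(float(ang),), t_start=t0, iti=3500)
        trials.append(tr)
        tgt = tr.target_xy(12.0)[0]
        saccades.append((tr.cue_onset + 300, 45, tgt))
        saccades.append((tr.t_end - tr.iti_ms + 250, 45, (0.0, 0.0)))
    proc = make_toy_proc(n_trials * step, saccades)
    return proc, trials


class TestRecalibration:
    def test_identity_noiseless(self):
        """Exact feedback fixations + identity warp -> identity fit, no change."""
        proc, trials = _toy_session()
        x0 = proc.x.copy()
        diag = recalibrate_run(proc, epochs_from_trials(trials), CFG)
        assert diag.applied and diag.n_pairs == 10
        np.testing.assert_allclose(diag.coeffs_x, (0, 1, 0, 0), atol=1e-6)
        np.testing.assert_allclose(diag.coeffs_y, (0, 1, 0, 0), atol=1e-6)
        assert diag.post_mean_dist < 1e-9
        np.testing.assert_allclose(proc.x, x0, atol=1e-9)

    def test_noisefree_simulated_run_already_calibrated(self, quiet_subject):
        """On an unwarped noise-free run the pairs are already near-perfect."""
        proc = quiet_subject["proc"]
        assert proc.recal.pre_mean_dist < 0.05
        # either an (accepted) near-identity fit or a rejected, no-op fit
        if not proc.recal.applied:
            assert proc.recal.flag == "fit_rejected"

    def test_cubic_warp_round_trip(self, one_run_design):
        params = SimulationParams(miscalibration_coeffs=WARP)
        trials, _, runs, _ = simulate_subject(one_run_design, params, seed=23)
        proc = preprocess_run(runs[0], epochs_from_trials(trials))
        assert proc.recal.applied
        assert proc.recal.post_mean_dist < 0.3
        assert proc.recal.post_mean_dist < proc.recal.pre_mean_dist

    def test_too_few_pairs_skips(self, quiet_params):
        design = TaskDesign(n_runs=1, trials_per_condition_per_run=2)  # 6 trials < 8
        trials, _, runs, _ = simulate_subject(design, quiet_params, seed=24)
        proc = preprocess_run(runs[0], epochs_from_trials(trials))
        assert not proc.recal.applied
        assert proc.recal.flag == "too_few_points"

    def test_epochs_are_condition_blind(self, quiet_subject):
        """Preprocessing inputs carry no condition information."""
        ep = epochs_from_trials(quiet_subject["trials"])[0]
        assert not hasattr(ep, "condition")
        assert not hasattr(ep, "cued_index")
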