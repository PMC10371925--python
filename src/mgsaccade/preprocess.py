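"""Automated, condition-blind gaze preprocessing.

Stages (in pipeline order):

1. **Blink masking** — samples whose pupil size falls strictly below the
   run-wise 1.5th percentile, padded by 200 ms on both sides, are marked
   invalid and excluded from every downstream computation.
2. **Smoothing and velocity** — per contiguous valid segment, x and y are
   smoothed with a Gaussian kernel (5-ms SD, truncated at 4 SD,
   renormalized near edges); speed is the Euclidean norm of the
   central-difference derivative, in deg/s. No interpolation across
   blinks: each valid segment is processed independently.
3. **Saccade/fixation segmentation** — a saccade's core is a maximal run
   of speed >= 30 deg/s; its extent is then refined outward to where
   speed stops decreasing or falls below an adaptive low threshold
   (max(core/3, 8% of the event's peak speed)), and the 7.5-ms duration
   and 0.25 deg displacement gates are applied to the refined extent.
   The refinement recovers the onsets of small saccades whose smoothed
   velocity crosses the core threshold only near their peak. Remaining
   valid time is tiled by fixations.
4. **Drift correction** — per trial, the centroid of the longest
   fixation in [trial start, response-cue onset) is subtracted from all
   of the trial's samples, re-zeroing the pre-cue fixation.
5. **Recalibration** — per trial, the feedback-epoch fixation closest to
   a target is paired with that target's true position; if at least
   ``recal_min_points`` pairs lie within ``recal_max_dist_deg``, one
   third-order polynomial per coordinate is fit (measured -> true, least
   squares) and applied to every sample of the run. A fit that does not
   improve the mean pair distance is discarded (flagged), so
   recalibration never degrades feedback-fixation accuracy.

No stage reads the trial condition: the interface accepts only epoch
times and target geometry (:class:`TrialEpochs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d

from .design import TrialSpec
from .gaze import GazeRun

__all__ = [
    "PreprocConfig",
    "Saccade",
    "Fixation",
    "EventSet",
    "TrialEpochs",
    "ProcessedRun",
    "EmptyRunError",
    "SamplingError",
    "epochs_from_trials",
    "detect_blinks",
    "smooth_and_velocity",
    "detect_saccades",
    "drift_correct",
    "recalibrate_run",
    "select_feedback_fixation",
    "preprocess_run",
]


class EmptyRunError(ValueError):
    """Raised when blink masking leaves no valid samples."""


class SamplingError(ValueError):
    """Raised when timestamps are not uniform 1000-Hz."""


@dataclass(frozen=True)
class PreprocConfig:
    blink_percentile: float = 1.5
    blink_pad_ms: int = 200
    smooth_sd_ms: float = 5.0
    vel_thresh_deg_s: float = 30.0
    sacc_min_dur_s: float = 0.0075
    sacc_min_amp_deg: float = 0.25
    recal_poly_order: int = 3
    recal_max_dist_deg: float = 2.5
    recal_min_points: int = 8
    # refinement of saccade extents beyond the core velocity threshold
    refine_low_frac: float = 0.08
    refine_floor_div: float = 3.0

    def validate(self) -> None:
        if not (0.0 < self.blink_percentile < 100.0):
            raise ValueError("blink_percentile must be in (0, 100)")
        for name in (
            "blink_pad_ms", "smooth_sd_ms", "vel_thresh_deg_s",
            "sacc_min_dur_s", "sacc_min_amp_deg", "recal_max_dist_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Saccade:
    i_on: int
    i_off: int
    onset_ms: int
    offset_ms: int
    amplitude_deg: float
    peak_velocity_deg_s: float

    @property
    def duration_ms(self) -> int:
        return self.i_off - self.i_on + 1


@dataclass
class Fixation:
    i_start: int
    i_end: int
    start_ms: int
    end_ms: int

    @property
    def duration_ms(self) -> int:
        return self.i_end - self.i_start + 1


@dataclass
class EventSet:
    """Blinks, saccades, and fixations segmented for one run.

    Saccade and fixation extents index into the run's sample arrays;
    positional attributes (endpoints, centroids) are always read from the
    *current* (possibly drift-corrected/recalibrated) traces so that
    corrections propagate without re-detection.
    """

    blinks: list[tuple[int, int]] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    fixations: list[Fixation] = field(default_factory=list)


@dataclass(frozen=True)
class TrialEpochs:
    """Condition-blind view of one trial: epoch times and target geometry."""

    trial_id: int
    t_start: int
    cue_onset: int
    feedback_onset: int
    feedback_end: int
    t_end: int
    target_xy: np.ndarray  # (n_targets, 2)


def epochs_from_trials(
    trials: list[TrialSpec], eccentricity_deg: float = 12.0
) -> list[TrialEpochs]:
    """Strip conditions from TrialSpecs, keeping only what preprocessing may see."""
    out = []
    for tr in trials:
        out.append(
            TrialEpochs(
                trial_id=tr.trial_id,
                t_start=tr.t_start,
                cue_onset=tr.cue_onset,
                feedback_onset=tr.feedback_onset,
                feedback_end=tr.t_end - tr.iti_ms,
                t_end=tr.t_end,
                target_xy=tr.target_xy(eccentricity_deg),
            )
        )
    return out


@dataclass
class ProcessedRun:
    """A run after preprocessing: working traces, validity, and events."""

    run_id: int
    t_ms: np.ndarray
    x: np.ndarray  # smoothed, drift-corrected, recalibrated
    y: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    speed: np.ndarray
    events: EventSet
    drift_offsets: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    recal: "RecalDiagnostics | None" = None

    def fixation_centroid(self, fix: Fixation) -> np.ndarray:
        sl = slice(fix.i_start, fix.i_end + 1)
        return np.array([self.x[sl].mean(), self.y[sl].mean()])

    def saccade_endpoint(self, sac: Saccade) -> np.ndarray:
        """Landing position of a saccade.

        Read from the post-saccadic fixation when one immediately follows
        (mean over up to 100 ms of it, skipping an 8-ms settle window);
        otherwise the position at the refined offset sample.
        """
        for fix in self.events.fixations:
            if fix.i_start == sac.i_off + 1:
                j0 = min(fix.i_start + 8, fix.i_end)
                j1 = min(fix.i_start + 108, fix.i_end)
                sl = slice(j0, j1 + 1)
                return np.array([self.x[sl].mean(), self.y[sl].mean()])
        return np.array([self.x[sac.i_off], self.y[sac.i_off]])

    def saccade_start(self, sac: Saccade) -> np.ndarray:
        return np.array([self.x[sac.i_on], self.y[sac.i_on]])


def detect_blinks(
    run: GazeRun, cfg: PreprocConfig
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Blink intervals (inclusive ms bounds) and the per-sample validity mask."""
    cfg.validate()
    if run.n_samples < 2:
        raise EmptyRunError("run has fewer than 2 samples")
    q = np.quantile(run.pupil, cfg.blink_percentile / 100.0)
    sub = run.pupil < q
    if not sub.any():
        return [], np.ones(run.n_samples, dtype=bool)
    pad = int(cfg.blink_pad_ms)
    invalid = maximum_filter1d(sub.astype(np.uint8), size=2 * pad + 1).astype(bool)
    if invalid.all():
        raise EmptyRunError("blink masking invalidated the entire run")
    idx = np.flatnonzero(invalid)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    intervals = [
        (int(run.t_ms[s]), int(run.t_ms[e])) for s, e in zip(starts, ends)
    ]
    return intervals, ~invalid


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _smooth_segment(v: np.ndarray, sd: float) -> np.ndarray:
    num = gaussian_filter1d(v, sd, mode="constant", cval=0.0, truncate=4.0)
    den = gaussian_filter1d(np.ones_like(v), sd, mode="constant", cval=0.0, truncate=4.0)
    return num / den


def smooth_and_velocity(
    run: GazeRun, valid: np.ndarray, cfg: PreprocConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed traces and speed (deg/s), per valid segment.

    Invalid (blink-masked) samples keep their raw positions and get
    speed 0; smoothing never crosses a blink gap.
    """
    cfg.validate()
    dt = np.diff(run.t_ms)
    if not np.all(dt == 1):
        raise SamplingError("timestamps must be uniform at 1 ms spacing")
    if run.t_ms[0] != 0:
        raise SamplingError("run time must start at 0 ms")
    xs = run.x.astype(float).copy()
    ys = run.y.astype(float).copy()
    speed = np.zeros(run.n_samples)
    for s, e in _valid_segments(valid):
        sl = slice(s, e + 1)
        if e - s + 1 < 3:
            continue
        xs[sl] = _smooth_segment(run.x[sl].astype(float), cfg.smooth_sd_ms)
        ys[sl] = _smooth_segment(run.y[sl].astype(float), cfg.smooth_sd_ms)
        vx = np.gradient(xs[sl]) * 1000.0
        vy = np.gradient(ys[sl]) * 1000.0
        speed[sl] = np.hypot(vx, vy)
    return xs, ys, speed


def detect_saccades(
    run: GazeRun,
    xs: np.ndarray,
    ys: np.ndarray,
    speed: np.ndarray,
    valid: np.ndarray,
    cfg: PreprocConfig,
    blinks: list[tuple[int, int]] | None = None,
) -> EventSet:
    """Segment each valid stretch into saccades and fixations."""
    cfg.validate()
    events = EventSet(blinks=list(blinks) if blinks else [])
    min_dur_samples = cfg.sacc_min_dur_s * 1000.0
    for s, e in _valid_segments(valid):
        seg_saccades: list[Saccade] = []
        sp = speed[s : e + 1]
        supra = sp >= cfg.vel_thresh_deg_s
        idx = np.flatnonzero(supra)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            core_on = np.concatenate([[idx[0]], idx[breaks + 1]]) + s
            core_off = np.concatenate([idx[breaks], [idx[-1]]]) + s
        else:
            core_on = core_off = np.array([], dtype=int)
        prev_off = s - 1
        for c0, c1 in zip(core_on, core_off):
            peak = float(speed[c0 : c1 + 1].max())
            low = max(cfg.vel_thresh_deg_s / cfg.refine_floor_div,
                      cfg.refine_low_frac * peak)
            i0, i1 = int(c0), int(c1)
            while i0 > prev_off + 1 and speed[i0 - 1] >= low and speed[i0 - 1] < speed[i0]:
                i0 -= 1
            while i1 < e and speed[i1 + 1] >= low and speed[i1 + 1] < speed[i1]:
                i1 += 1
            if i1 - i0 + 1 < min_dur_samples:
                continue
            # displacement measured slightly outside the refined extent to
            # include the sub-threshold tails of the movement
            j0 = max(i0 - 8, s, prev_off + 1)
            j1 = min(i1 + 8, e)
            disp = float(np.hypot(xs[j1] - xs[j0], ys[j1] - ys[j0]))
            if disp < cfg.sacc_min_amp_deg:
                continue
            if seg_saccades and i0 <= seg_saccades[-1].i_off:
                i0 = seg_saccades[-1].i_off + 1
            seg_saccades.append(
                Saccade(
                    i_on=i0,
                    i_off=i1,
                    onset_ms=int(run.t_ms[i0]),
                    offset_ms=int(run.t_ms[i1]),
                    amplitude_deg=disp,
                    peak_velocity_deg_s=peak,
                )
            )
            prev_off = i1
        # fixations tile the rest of the segment
        cursor = s
        for sac in seg_saccades:
            if sac.i_on > cursor:
                events.fixations.append(
                    Fixation(cursor, sac.i_on - 1,
                             int(run.t_ms[cursor]), int(run.t_ms[sac.i_on - 1]))
                )
            cursor = sac.i_off + 1
        if cursor <= e:
            events.fixations.append(
                Fixation(cursor, e, int(run.t_ms[cursor]), int(run.t_ms[e]))
            )
        events.saccades.extend(seg_saccades)
    return events


def _overlap_samples(fix: Fixation, t0: int, t1: int) -> tuple[int, int] | None:
    """Index bounds of fix ∩ [t0, t1) or None (sample index == time here)."""
    a = max(fix.i_start, t0)
    b = min(fix.i_end, t1 - 1)
    if b < a:
        return None
    return a, b


def drift_correct(proc: ProcessedRun, epochs: list[TrialEpochs]) -> ProcessedRun:
    """Re-zero each trial on its pre-cue fixation position (in place).

    The "modal" pre-cue position is taken as the centroid of the fixation
    with the longest overlap with [trial start, cue onset). Trials with no
    pre-cue fixation are flagged and left uncorrected. Idempotent: a
    second pass subtracts (numerically) zero.
    """
    for ep in epochs:
        best = None
        best_len = 0
        for fix in proc.events.fixations:
            ov = _overlap_samples(fix, ep.t_start, ep.cue_onset)
            if ov and (ov[1] - ov[0] + 1) > best_len:
                best, best_len = ov, ov[1] - ov[0] + 1
        if best is None:
            proc.flags.setdefault("no_precue_fixation", []).append(ep.trial_id)
            continue
        a, b = best
        off = np.array([proc.x[a : b + 1].mean(), proc.y[a : b + 1].mean()])
        sl = slice(ep.t_start, ep.t_end)
        proc.x[sl] -= off[0]
        proc.y[sl] -= off[1]
        prev = np.array(proc.drift_offsets.get(ep.trial_id, (0.0, 0.0)))
        proc.drift_offsets[ep.trial_id] = tuple(prev + off)
    return proc


def select_feedback_fixation(
    proc: ProcessedRun, ep: TrialEpochs, min_overlap_ms: int = 50
) -> tuple[Fixation, np.ndarray, int, float] | None:
    """Feedback-epoch fixation closest to a target.

    Returns (fixation, centroid over the feedback-epoch overlap, index of
    the nearest target, distance to it), or None if no fixation overlaps
    the feedback epoch by at least ``min_overlap_ms``. Ties in target
    distance resolve to the lower target index.
    """
    best = None
    for fix in proc.events.fixations:
        ov = _overlap_samples(fix, ep.feedback_onset, ep.feedback_end)
        if ov is None or (ov[1] - ov[0] + 1) < min_overlap_ms:
            continue
        a, b = ov
        # skip the post-saccadic settle at the head of a fresh fixation
        if a == fix.i_start and b - a > 20:
            a += 10
        cen = np.array([proc.x[a : b + 1].mean(), proc.y[a : b + 1].mean()])
        d = np.hypot(*(ep.target_xy - cen).T)
        k = int(np.argmin(d))
        if best is None or d[k] < best[3]:
            best = (fix, cen, k, float(d[k]))
    return best


@dataclass
class RecalDiagnostics:
    applied: bool
    n_pairs: int
    coeffs_x: tuple[float, ...] | None
    coeffs_y: tuple[float, ...] | None
    pre_mean_dist: float | None
    post_mean_dist: float | None
    flag: str | None = None


def recalibrate_run(
    proc: ProcessedRun, epochs: list[TrialEpochs], cfg: PreprocConfig
) -> RecalDiagnostics:
    """Fit and apply the per-run cubic recalibration (in place).

    Pairs each trial's selected feedback fixation with the true position
    of its nearest target; keeps pairs within ``recal_max_dist_deg``; fits
    one order-``recal_poly_order`` polynomial per coordinate mapping
    measured -> true and applies it to every sample. Skipped (flagged) if
    fewer than ``recal_min_points`` pairs survive, if the fit is
    ill-conditioned, or if it fails to improve the mean pair distance.
    """
    cfg.validate()
    measured, true = [], []
    for ep in epochs:
        sel = select_feedback_fixation(proc, ep)
        if sel is None:
            continue
        _, cen, k, d = sel
        if d <= cfg.recal_max_dist_deg:
            measured.append(cen)
            true.append(ep.target_xy[k])
    n_pairs = len(measured)
    if n_pairs < cfg.recal_min_points:
        diag = RecalDiagnostics(False, n_pairs, None, None, None, None,
                                flag="too_few_points")
        proc.recal = diag
        return diag
    m = np.array(measured)
    tgt = np.array(true)
    pre = float(np.hypot(*(m - tgt).T).mean())
    order = cfg.recal_poly_order
    try:
        with np.errstate(all="ignore"):
            px = np.polynomial.polynomial.polyfit(m[:, 0], tgt[:, 0], order)
            py = np.polynomial.polynomial.polyfit(m[:, 1], tgt[:, 1], order)
    except np.linalg.LinAlgError:
        diag = RecalDiagnostics(False, n_pairs, None, None, pre, None,
                                flag="ill_conditioned")
        proc.recal = diag
        return diag
    if not (np.all(np.isfinite(px)) and np.all(np.isfinite(py))):
        diag = RecalDiagnostics(False, n_pairs, None, None, pre, None,
                                flag="ill_conditioned")
        proc.recal = diag
        return diag
    mx = np.polynomial.polynomial.polyval(m[:, 0], px)
    my = np.polynomial.polynomial.polyval(m[:, 1], py)
    post = float(np.hypot(mx - tgt[:, 0], my - tgt[:, 1]).mean())
    if post > pre + 1e-6:
        diag = RecalDiagnostics(False, n_pairs, tuple(px), tuple(py), pre, post,
                                flag="fit_rejected")
        proc.recal = diag
        return diag
    proc.x = np.polynomial.polynomial.polyval(proc.x, px)
    proc.y = np.polynomial.polynomial.polyval(proc.y, py)
    diag = RecalDiagnostics(True, n_pairs, tuple(px), tuple(py), pre, post)
    proc.recal = diag
    return diag


def preprocess_run(
    run: GazeRun, epochs: list[TrialEpochs], cfg: PreprocConfig | None = None
) -> ProcessedRun:
    """Full preprocessing chain for one run."""
    cfg = cfg or PreprocConfig()
    blinks, valid = detect_blinks(run, cfg)
    xs, ys, speed = smooth_and_velocity(run, valid, cfg)
    events = detect_saccades(run, xs, ys, speed, valid, cfg, blinks=blinks)
    proc = ProcessedRun(
        run_id=run.run_id,
        t_ms=run.t_ms,
        x=xs,
        y=ys,
        pupil=run.pupil,
        valid=valid,
        speed=speed,
        events=events,
    )
    drift_correct(proc, epochs)
    recalibrate_run(proc, epochs, cfg)
    return proc
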