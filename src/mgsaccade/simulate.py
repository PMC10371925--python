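"""Synthetic memory-guided saccade experiment with full ground truth.

The generative model has two layers:

1. **Memory layer** — a variable-precision account of spatial working
   memory. Each remembered item on each trial gets an encoding precision
   ``J`` drawn from a gamma distribution whose scale is set per
   condition-role so that the mean of the implied report noise
   ``sd = 1/sqrt(J)`` equals the configured condition value. The memory
   report is the true location plus isotropic Gaussian error at that sd.
   On R2-best trials the chooser picks the item with the smaller *drawn*
   sd (introspection of representation quality, not oracle access to the
   realized error), lapsing to a random item with probability
   ``choice_lapse``. Alternative choosers (location-heuristic, random)
   are available for testing choice-strategy analyses.

2. **Oculomotor layer** — 1000-Hz gaze traces: fixational jitter around
   fixation, a main-sequence response saccade launched at a
   condition-dependent latency toward the report location (logistic
   position profile; duration 2.2 ms/deg x amplitude + 21 ms), an
   optional corrective saccade, a feedback-epoch fixation on the
   re-presented reported target, blinks as pupil dropouts, a constant
   per-trial drift offset, and finally a per-run cubic miscalibration
   warp applied to all samples.

Everything is driven by a single ``numpy`` Generator, so identical
(design, params, seed) produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import CONDITIONS, TaskDesign, TrialSpec, generate_design, polar_to_xy
from .gaze import GazeRun

__all__ = [
    "SimulationParams",
    "ReportDraw",
    "SimTruth",
    "simulate_memory_report",
    "simulate_gaze",
    "apply_miscalibration",
    "gamma_scale_for_mean_sd",
    "simulate_report_errors",
    "simulate_scored_cohort",
]

IDENTITY_COEFFS = (0.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of the synthetic experiment.

    ``memory_sd_mean_deg`` gives the mean report-noise sd per
    condition-role: key ``"R1"`` for the single item on R1 trials and
    ``"R2"`` for each of the two items on R2 trials (the set-size effect
    is expressed as a larger R2 value). ``precision_shape`` is the gamma
    shape of the per-trial precision distribution (must be > 0.5; smaller
    values mean stronger trial-to-trial fluctuation). RT parameters are
    per condition; latencies are drawn Gaussian and clipped to
    ``rt_clip_ms``. ``miscalibration_coeffs`` are ascending-power cubic
    coefficient vectors for the x and y channels.
    """

    memory_sd_mean_deg: dict = field(
        default_factory=lambda: {"R1": 0.8, "R2": 1.3}
    )
    precision_shape: float = 3.0
    choice_lapse: float = 0.1
    choice_policy: str = "precision"  # "precision" | "location" | "random"
    location_mod_amp: float = 0.0
    location_mod_phase_deg: float = 0.0
    rt_mean_ms: dict = field(
        default_factory=lambda: {"R1": 300.0, "R2-random": 380.0, "R2-best": 480.0}
    )
    rt_sd_ms: float = 80.0
    rt_clip_ms: tuple[float, float] = (120.0, 1400.0)
    rt_lapse_prob: float = 0.03  # attentional lapses: occasional slow responses
    fixation_break_prob: float = 0.02  # delay-epoch fixation-break excursions
    saccade_dur_slope_ms_per_deg: float = 2.2
    saccade_dur_intercept_ms: float = 21.0
    saccade_steepness: float = 9.0
    saccade_gain: float = 0.9
    corrective_prob: float = 0.7
    corrective_delay_ms: tuple[int, int] = (120, 220)
    feedback_latency_ms: float = 200.0
    fixation_jitter_sd_deg: float = 0.05
    blink_rate_hz: float = 0.1
    blink_dur_ms: tuple[int, int] = (80, 120)
    drift_sd_deg: float = 0.3
    miscalibration_coeffs: tuple[tuple[float, ...], tuple[float, ...]] = (
        IDENTITY_COEFFS,
        IDENTITY_COEFFS,
    )
    pupil_baseline: float = 1000.0
    pupil_fluct: float = 1.0  # scales slow pupil oscillation + sample noise
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.choice_lapse <= 1.0):
            raise ValueError("choice_lapse must be in [0, 1]")
        if self.choice_policy not in ("precision", "location", "random"):
            raise ValueError(f"unknown choice_policy {self.choice_policy!r}")
        if self.precision_shape <= 0.5:
            raise ValueError("precision_shape must exceed 0.5 for a finite mean sd")
        for k, v in self.memory_sd_mean_deg.items():
            if v < 0:
                raise ValueError(f"memory_sd_mean_deg[{k!r}] must be >= 0")
        if self.fixation_jitter_sd_deg < 0 or self.drift_sd_deg < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.location_mod_amp < 1.0):
            raise ValueError("location_mod_amp must be in [0, 1)")


@dataclass(frozen=True)
class ReportDraw:
    """Memory-layer outcome for one trial."""

    report_index: int
    report_xy: tuple[float, float]
    item_sds: tuple[float, ...]
    item_errors: tuple[tuple[float, float], ...]
    lapsed: bool


@dataclass
class SimTruth:
    """Ground truth: per-trial table, every injected saccade, per-run warps."""

    trials: pd.DataFrame
    saccades: pd.DataFrame
    warp_coeffs: dict


def gamma_scale_for_mean_sd(mean_sd: float, shape: float) -> float:
    """Gamma scale such that E[J^(-1/2)] = mean_sd for J ~ Gamma(shape, scale)."""
    if mean_sd <= 0:
        return 0.0
    # E[J^(-1/2)] = scale^(-1/2) * Gamma(shape - 1/2) / Gamma(shape)
    log_ratio = gammaln(shape - 0.5) - gammaln(shape)
    return float(np.exp(2.0 * (log_ratio - np.log(mean_sd))))


def _sd_multiplier(angles_deg: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Smooth polar-angle modulation of memory noise (1 when amp = 0)."""
    if params.location_mod_amp == 0.0:
        return np.ones_like(np.asarray(angles_deg, dtype=float))
    rad = np.radians(np.asarray(angles_deg, dtype=float) - params.location_mod_phase_deg)
    return 1.0 + params.location_mod_amp * np.cos(rad)


def _draw_item_sds(
    angles_deg: np.ndarray, role: str, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    mean_sd = params.memory_sd_mean_deg[role] * _sd_multiplier(angles_deg, params)
    out = np.zeros(len(mean_sd))
    pos = mean_sd > 0
    if np.any(pos):
        scale = np.array(
            [gamma_scale_for_mean_sd(m, params.precision_shape) for m in mean_sd[pos]]
        )
        J = rng.gamma(params.precision_shape, scale)
        out[pos] = 1.0 / np.sqrt(J)
    return out


def simulate_memory_report(
    trial: TrialSpec,
    params: SimulationParams,
    rng: np.random.Generator,
    eccentricity_deg: float = 12.0,
) -> ReportDraw:
    """Draw per-item precisions and the reported location for one trial."""
    params.validate()
    angles = np.asarray(trial.target_angles_deg)
    role = "R1" if trial.condition == "R1" else "R2"
    sds = _draw_item_sds(angles, role, params, rng)
    errors = rng.normal(0.0, 1.0, size=(len(angles), 2)) * sds[:, None]

    lapsed = False
    if trial.condition in ("R1", "R2-random"):
        idx = int(trial.cued_index)
    else:
        if params.choice_policy == "random":
            idx = int(rng.integers(0, len(angles)))
        elif params.choice_policy == "location":
            idx = int(np.argmin(_sd_multiplier(angles, params)))
        else:
            idx = int(np.argmin(sds))
        if params.choice_lapse > 0 and rng.random() < params.choice_lapse:
            idx = int(rng.integers(0, len(angles)))
            lapsed = True

    true_xy = np.array(polar_to_xy(eccentricity_deg, angles[idx]))
    report = true_xy + errors[idx]
    return ReportDraw(
        report_index=idx,
        report_xy=(float(report[0]), float(report[1])),
        item_sds=tuple(float(s) for s in sds),
        item_errors=tuple((float(e[0]), float(e[1])) for e in errors),
        lapsed=lapsed,
    )


def apply_miscalibration(
    x: np.ndarray, y: np.ndarray, coeffs: tuple[tuple[float, ...], tuple[float, ...]]
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the per-channel cubic warp sample-wise (ascending-power coeffs)."""
    cx, cy = coeffs
    xw = np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), np.asarray(cx))
    yw = np.polynomial.polynomial.polyval(np.asarray(y, dtype=float), np.asarray(cy))
    return xw, yw


def _logistic_segment(amp_xy: np.ndarray, dur: int, steepness: float) -> np.ndarray:
    """(dur+1, 2) displacement profile from 0 to amp_xy, normalized logistic."""
    tau = np.arange(dur + 1, dtype=float)
    c = steepness
    p0 = 1.0 / (1.0 + math.exp(c / 2.0))
    p = 1.0 / (1.0 + np.exp(-c * (tau - dur / 2.0) / dur))
    frac = (p - p0) / (1.0 - 2.0 * p0)
    return frac[:, None] * amp_xy[None, :]


class _TraceBuilder:
    """Fills a run-long position array from a sequence of saccade commands."""

    def __init__(self, n: int, params: SimulationParams):
        self.pos = np.zeros((n, 2))
        self.params = params
        self.cursor_t = 0
        self.cursor_xy = np.zeros(2)
        self.n = n
        self.log: list[dict] = []

    def saccade(
        self, onset: int, to_xy: np.ndarray, label: str = "", trial_id: int = -1
    ) -> tuple[int, int]:
        """Hold position until ``onset``, then move to ``to_xy``.

        Returns (actual_onset, offset); onset is pushed later if it would
        overlap the previous movement. Every movement is logged as ground
        truth (label, trial, onset, offset, amplitude).
        """
        onset = max(int(onset), self.cursor_t + 2)
        amp_vec = np.asarray(to_xy, dtype=float) - self.cursor_xy
        amp = float(np.hypot(*amp_vec))
        p = self.params
        dur = max(
            4, int(round(p.saccade_dur_slope_ms_per_deg * amp + p.saccade_dur_intercept_ms))
        )
        if onset >= self.n:
            return self.n - 1, self.n - 1
        self.pos[self.cursor_t : onset] = self.cursor_xy
        end = min(onset + dur, self.n - 1)
        seg = _logistic_segment(amp_vec, dur, p.saccade_steepness)
        self.pos[onset : end + 1] = self.cursor_xy + seg[: end + 1 - onset]
        self.cursor_t = end + 1
        self.cursor_xy = self.cursor_xy + amp_vec
        self.log.append({
            "trial_id": trial_id, "label": label, "onset_ms": onset,
            "offset_ms": end, "amplitude_deg": amp,
        })
        return onset, end

    def finish(self) -> np.ndarray:
        self.pos[self.cursor_t :] = self.cursor_xy
        return self.pos


def _simulate_run(
    run_trials: list[TrialSpec],
    reports: list[ReportDraw],
    params: SimulationParams,
    rng: np.random.Generator,
    eccentricity_deg: float,
) -> tuple[GazeRun, list[dict]]:
    run_id = run_trials[0].run_id
    n = run_trials[-1].t_end
    builder = _TraceBuilder(n, params)
    truth_rows: list[dict] = []

    for trial, rep in zip(run_trials, reports):
        rt = rng.normal(params.rt_mean_ms[trial.condition], params.rt_sd_ms)
        if params.rt_lapse_prob > 0 and rng.random() < params.rt_lapse_prob:
            rt += rng.uniform(250.0, 600.0)
        rt = float(np.clip(rt, *params.rt_clip_ms))
        onset_nominal = int(round(trial.cue_onset + rt))

        if (
            params.fixation_break_prob > 0
            and rng.random() < params.fixation_break_prob
        ):
            # brief excursion away from fixation during the memory delay
            t_break = int(trial.t_start + 500 + rng.uniform(400, 2600))
            ang = rng.uniform(0, 2 * np.pi)
            ecc = rng.uniform(3.0, 5.0)
            away = np.array([ecc * np.cos(ang), ecc * np.sin(ang)])
            _, b_off = builder.saccade(t_break, away, "break", trial.trial_id)
            builder.saccade(
                b_off + int(rng.uniform(200, 400)), np.zeros(2),
                "break_return", trial.trial_id,
            )
        report_xy = np.array(rep.report_xy)
        make_corrective = (
            params.corrective_prob > 0
            and rng.random() < params.corrective_prob
            and params.saccade_gain != 1.0
        )
        primary_target = (
            report_xy * params.saccade_gain if make_corrective else report_xy
        )
        onset, offset = builder.saccade(
            onset_nominal, primary_target, "primary", trial.trial_id
        )
        if make_corrective:
            delay = int(rng.integers(*params.corrective_delay_ms))
            builder.saccade(offset + delay, report_xy, "corrective", trial.trial_id)

        true_target = np.array(
            polar_to_xy(eccentricity_deg, trial.target_angles_deg[rep.report_index])
        )
        fb_latency = int(
            round(max(80.0, rng.normal(params.feedback_latency_ms, 30.0)))
        )
        if np.hypot(*(true_target - builder.cursor_xy)) > 0.3:
            builder.saccade(
                trial.feedback_onset + fb_latency, true_target,
                "feedback", trial.trial_id,
            )
        # return to fixation shortly after the feedback epoch ends
        ret_latency = int(round(max(80.0, rng.normal(250.0, 50.0))))
        builder.saccade(
            (trial.t_end - trial.iti_ms) + ret_latency, np.zeros(2),
            "return", trial.trial_id,
        )

        truth_rows.append(
            {
                "run_id": run_id,
                "trial_id": trial.trial_id,
                "condition": trial.condition,
                "report_index": rep.report_index,
                "report_x": rep.report_xy[0],
                "report_y": rep.report_xy[1],
                "true_onset_ms": onset,
                "rt_true_ms": onset - trial.cue_onset,
                "sd_items": ";".join(f"{s:.6g}" for s in rep.item_sds),
                "lapsed": rep.lapsed,
            }
        )

    pos = builder.finish()
    x, y = pos[:, 0].copy(), pos[:, 1].copy()

    if params.fixation_jitter_sd_deg > 0:
        x += rng.normal(0.0, params.fixation_jitter_sd_deg, n)
        y += rng.normal(0.0, params.fixation_jitter_sd_deg, n)

    for i, trial in enumerate(run_trials):
        if params.drift_sd_deg > 0:
            dxy = rng.normal(0.0, params.drift_sd_deg, 2)
        else:
            dxy = np.zeros(2)
        x[trial.t_start : trial.t_end] += dxy[0]
        y[trial.t_start : trial.t_end] += dxy[1]
        truth_rows[i]["drift_x"] = float(dxy[0])
        truth_rows[i]["drift_y"] = float(dxy[1])

    t = np.arange(n, dtype=np.int64)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    pupil = np.full(n, params.pupil_baseline)
    if params.pupil_fluct > 0:
        # slow oscillation so the sub-percentile tail clusters in a few dips
        pupil = pupil + params.pupil_fluct * (
            25.0 * np.sin(2 * np.pi * 0.02 * t / 1000.0 + ph1)
            + 15.0 * np.sin(2 * np.pi * 0.0077 * t / 1000.0 + ph2)
            + rng.normal(0.0, 2.0, n)
        )
    n_blinks = rng.poisson(params.blink_rate_hz * n / 1000.0)
    for _ in range(n_blinks):
        s = int(rng.integers(0, n))
        d = int(rng.integers(*params.blink_dur_ms))
        pupil[s : s + d] = 0.0

    xw, yw = apply_miscalibration(x, y, params.miscalibration_coeffs)
    sacc_rows = [dict(run_id=run_id, **r) for r in builder.log]
    return GazeRun(run_id, t, xw, yw, pupil), truth_rows, sacc_rows


def simulate_gaze(
    trials: list[TrialSpec],
    reports: list[ReportDraw],
    params: SimulationParams,
    rng: np.random.Generator,
    eccentricity_deg: float = 12.0,
) -> tuple[list[GazeRun], SimTruth]:
    """Synthesize 1000-Hz gaze recordings for all runs in ``trials``.

    ``reports`` must align one-to-one with ``trials`` (see
    :func:`simulate_memory_report`). Returns one :class:`GazeRun` per run
    plus the ground-truth table.
    """
    params.validate()
    if len(trials) != len(reports):
        raise ValueError("trials and reports must align one-to-one")
    runs: list[GazeRun] = []
    rows: list[dict] = []
    sacc_rows: list[dict] = []
    warps: dict = {}
    run_ids = sorted({tr.run_id for tr in trials})
    for rid in run_ids:
        sel = [i for i, tr in enumerate(trials) if tr.run_id == rid]
        gr, tr_rows, s_rows = _simulate_run(
            [trials[i] for i in sel], [reports[i] for i in sel], params, rng,
            eccentricity_deg,
        )
        runs.append(gr)
        rows.extend(tr_rows)
        sacc_rows.extend(s_rows)
        warps[rid] = params.miscalibration_coeffs
    return runs, SimTruth(
        trials=pd.DataFrame(rows),
        saccades=pd.DataFrame(sacc_rows),
        warp_coeffs=warps,
    )


# ---------------------------------------------------------------------------
# Vectorized report-level cohort simulation (for statistics calibration)
# ---------------------------------------------------------------------------

def simulate_report_errors(
    n_trials: int,
    condition: str,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euclidean report errors (deg) for ``n_trials`` of one condition.

    Runs the memory layer only, fully vectorized — the same generative
    model as :func:`simulate_memory_report` with uniform target angles and
    the separation constraint (which does not enter the error model).
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_items = 1 if condition == "R1" else 2
    role = "R1" if condition == "R1" else "R2"
    angles = rng.uniform(0.0, 360.0, size=(n_trials, n_items))
    mean_sd = params.memory_sd_mean_deg[role] * _sd_multiplier(angles, params)
    shape = params.precision_shape
    log_ratio = gammaln(shape - 0.5) - gammaln(shape)
    with np.errstate(divide="ignore"):
        scale = np.exp(2.0 * (log_ratio - np.log(mean_sd)))
    J = rng.gamma(shape, np.where(mean_sd > 0, scale, 1.0))
    sds = np.where(mean_sd > 0, 1.0 / np.sqrt(J), 0.0)
    errors = rng.normal(0.0, 1.0, size=(n_trials, n_items, 2)) * sds[..., None]

    if condition == "R1":
        idx = np.zeros(n_trials, dtype=int)
    elif condition == "R2-random":
        idx = rng.integers(0, 2, n_trials)
    else:
        if params.choice_policy == "random":
            idx = rng.integers(0, 2, n_trials)
        elif params.choice_policy == "location":
            idx = np.argmin(_sd_multiplier(angles, params), axis=1)
        else:
            idx = np.argmin(sds, axis=1)
        if params.choice_lapse > 0:
            lapse = rng.random(n_trials) < params.choice_lapse
            idx = np.where(lapse, rng.integers(0, 2, n_trials), idx)
    picked = errors[np.arange(n_trials), idx]
    return np.hypot(picked[:, 0], picked[:, 1])


def simulate_scored_cohort(
    n_subjects: int,
    trials_per_condition: int,
    params: SimulationParams,
    seed: int | np.random.Generator,
    exclusion_rate: float = 0.15,
    eccentricity_deg: float = 12.0,
) -> pd.DataFrame:
    """Report-level scored-trial table for a cohort (memory layer only).

    Produces the same columns the full pipeline's scorer emits, with RTs
    drawn from the latency model and a condition-independent Bernoulli
    exclusion hazard. Intended for calibration and recovery studies of the
    statistics layer at realistic trial counts without gaze synthesis.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params.validate()
    rows = []
    for subj in range(n_subjects):
        for cond in CONDITIONS:
            n = trials_per_condition
            n_items = 1 if cond == "R1" else 2
            role = "R1" if cond == "R1" else "R2"
            angles = rng.uniform(0.0, 360.0, size=(n, n_items))
            mean_sd = params.memory_sd_mean_deg[role] * _sd_multiplier(angles, params)
            shape = params.precision_shape
            log_ratio = gammaln(shape - 0.5) - gammaln(shape)
            with np.errstate(divide="ignore"):
                scale = np.exp(2.0 * (log_ratio - np.log(mean_sd)))
            J = rng.gamma(shape, np.where(mean_sd > 0, scale, 1.0))
            sds = np.where(mean_sd > 0, 1.0 / np.sqrt(J), 0.0)
            errors = rng.normal(0.0, 1.0, size=(n, n_items, 2)) * sds[..., None]
            if cond == "R1":
                idx = np.zeros(n, dtype=int)
            elif cond == "R2-random":
                idx = rng.integers(0, 2, n)
            else:
                if params.choice_policy == "random":
                    idx = rng.integers(0, 2, n)
                elif params.choice_policy == "location":
                    idx = np.argmin(_sd_multiplier(angles, params), axis=1)
                else:
                    idx = np.argmin(sds, axis=1)
                if params.choice_lapse > 0:
                    lapse = rng.random(n) < params.choice_lapse
                    idx = np.where(lapse, rng.integers(0, 2, n), idx)
            ar = np.arange(n)
            rep_angle = angles[ar, idx]
            err = errors[ar, idx]
            tx = eccentricity_deg * np.cos(np.radians(rep_angle))
            ty = eccentricity_deg * np.sin(np.radians(rep_angle))
            rts = np.clip(
                rng.normal(params.rt_mean_ms[cond], params.rt_sd_ms, n),
                *params.rt_clip_ms,
            )
            excluded = rng.random(n) < exclusion_rate
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "condition": cond,
                        "trial": ar,
                        "reported_angle_deg": rep_angle,
                        "target_angle_0": angles[:, 0],
                        "target_angle_1": angles[:, 1] if n_items > 1 else np.nan,
                        "target_x": tx,
                        "target_y": ty,
                        "final_x": tx + err[:, 0],
                        "final_y": ty + err[:, 1],
                        "recall_error_deg": np.hypot(err[:, 0], err[:, 1]),
                        "rt_ms": rts,
                        "n_saccades": 1 + rng.poisson(0.8, n),
                        "excluded": excluded,
                        "exclusion_reason": np.where(excluded, "rt_out_of_range", "none"),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
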