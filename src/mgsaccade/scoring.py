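"""Blinded per-trial scoring of memory-guided saccades.

For each trial the scorer labels the **initial** saccade (the first
saccade after the response cue with amplitude > 5 deg and duration
< 150 ms — the ballistic memory-guided response) and the **final**
saccade (the last saccade before feedback; identical to the initial one
when no corrective saccade was made). From these it derives:

* ``rt_ms`` — response cue onset to initial-saccade onset;
* ``recall_error_deg`` — Euclidean distance between the final-saccade
  endpoint and the true location of the reported target;
* ``n_saccades`` — all detected saccades between cue and feedback onset.

On R1/R2-random trials the reported target is the cued one; on R2-best
trials it is the target nearest the feedback-epoch fixation (the same
fixation-selection rule recalibration uses), falling back to the target
nearest the final-saccade endpoint when no feedback fixation exists.

Three blinded exclusion rules are applied in order (the first to fire is
recorded): (1) fixation break beyond 2.5 deg during the target or delay
epochs; (2) initial-saccade RT below 100 ms or above 1 s; (3) no
qualifying initial saccade, or an initial saccade landing more than
5 deg from every target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialSpec
from .preprocess import (
    ProcessedRun,
    Saccade,
    TrialEpochs,
    epochs_from_trials,
    select_feedback_fixation,
)

__all__ = [
    "ScoreConfig",
    "ScoredTrial",
    "label_saccades",
    "attribute_reported_target",
    "score_trial",
    "apply_exclusions",
    "score_run",
    "scored_to_frame",
]

EXCLUSION_REASONS = (
    "fixation_break",
    "rt_out_of_range",
    "no_or_erroneous_initial_saccade",
    "none",
)


@dataclass(frozen=True)
class ScoreConfig:
    init_min_amp_deg: float = 5.0
    init_max_dur_ms: float = 150.0
    rt_min_ms: float = 100.0
    rt_max_ms: float = 1000.0
    fixwin_deg: float = 2.5
    err_max_deg: float = 5.0

    def validate(self) -> None:
        if self.rt_min_ms >= self.rt_max_ms:
            raise ValueError("rt_min_ms must be < rt_max_ms")
        for name in ("init_min_amp_deg", "init_max_dur_ms", "rt_min_ms",
                     "fixwin_deg", "err_max_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScoredTrial:
    run_id: int
    trial_id: int
    condition: str
    reported_index: int | None
    reported_angle_deg: float | None
    target_x: float | None
    target_y: float | None
    final_x: float | None
    final_y: float | None
    rt_ms: float | None
    recall_error_deg: float | None
    n_saccades: int
    excluded: bool
    exclusion_reason: str
    target_angle_0: float = np.nan
    target_angle_1: float = np.nan
    attribution_fallback: bool = False


def _trial_saccades(proc: ProcessedRun, ep: TrialEpochs) -> list[Saccade]:
    return [
        s for s in proc.events.saccades
        if ep.cue_onset <= s.onset_ms and s.onset_ms < ep.feedback_onset
    ]


def label_saccades(
    proc: ProcessedRun, ep: TrialEpochs, cfg: ScoreConfig
) -> tuple[Saccade | None, Saccade | None]:
    """(initial, final) response saccades for a trial; either may be None.

    initial: first saccade at/after cue with amplitude > ``init_min_amp_deg``
    and duration < ``init_max_dur_ms``; final: last saccade whose offset
    precedes feedback onset. With no corrective saccade they coincide.
    """
    cfg.validate()
    cands = _trial_saccades(proc, ep)
    initial = None
    for s in cands:
        if (s.amplitude_deg > cfg.init_min_amp_deg
                and s.duration_ms < cfg.init_max_dur_ms):
            initial = s
            break
    final = None
    for s in cands:
        if s.offset_ms < ep.feedback_onset:
            final = s
    if final is None or (initial is not None and final.onset_ms < initial.onset_ms):
        final = initial
    return initial, final


def attribute_reported_target(
    trial: TrialSpec,
    proc: ProcessedRun,
    ep: TrialEpochs,
    final: Saccade | None,
) -> tuple[int | None, bool]:
    """(reported target index, fallback flag).

    R1/R2-random report the cued item; R2-best reports the target nearest
    the selected feedback fixation, or — flagged fallback — the target
    nearest the final-saccade endpoint.
    """
    if trial.condition in ("R1", "R2-random"):
        return int(trial.cued_index), False
    sel = select_feedback_fixation(proc, ep)
    if sel is not None:
        return sel[2], False
    if final is not None:
        end = proc.saccade_endpoint(final)
        d = np.hypot(*(ep.target_xy - end).T)
        return int(np.argmin(d)), True
    return None, True


def score_trial(
    trial: TrialSpec,
    proc: ProcessedRun,
    ep: TrialEpochs,
    initial: Saccade | None,
    final: Saccade | None,
    reported_index: int | None,
    cfg: ScoreConfig,
    fallback: bool = False,
) -> ScoredTrial:
    """Assemble RT, recall error, and saccade count for one trial."""
    rt = float(initial.onset_ms - ep.cue_onset) if initial is not None else None
    n_sacc = len(_trial_saccades(proc, ep))
    err = fx = fy = tx = ty = ang = None
    if final is not None and reported_index is not None:
        end = proc.saccade_endpoint(final)
        tgt = ep.target_xy[reported_index]
        err = float(np.hypot(*(end - tgt)))
        fx, fy = float(end[0]), float(end[1])
        tx, ty = float(tgt[0]), float(tgt[1])
        ang = float(trial.target_angles_deg[reported_index])
    return ScoredTrial(
        run_id=trial.run_id,
        trial_id=trial.trial_id,
        condition=trial.condition,
        reported_index=reported_index,
        reported_angle_deg=ang,
        target_x=tx,
        target_y=ty,
        final_x=fx,
        final_y=fy,
        rt_ms=rt,
        recall_error_deg=err,
        n_saccades=n_sacc,
        excluded=False,
        exclusion_reason="none",
        target_angle_0=float(trial.target_angles_deg[0]),
        target_angle_1=(
            float(trial.target_angles_deg[1]) if trial.n_targets > 1 else np.nan
        ),
        attribution_fallback=fallback,
    )


def apply_exclusions(
    scored: ScoredTrial,
    proc: ProcessedRun,
    ep: TrialEpochs,
    initial: Saccade | None,
    cfg: ScoreConfig,
) -> ScoredTrial:
    """Set the exclusion flag/reason on a scored trial (rules in order 1-3)."""
    cfg.validate()
    reason = None
    # rule 1: fixation break during target presentation or delay
    sl = slice(ep.t_start, ep.cue_onset)
    ok = proc.valid[sl]
    ecc = np.hypot(proc.x[sl][ok], proc.y[sl][ok])
    if ecc.size and np.any(ecc > cfg.fixwin_deg):
        reason = "fixation_break"
    # rule 2: initial-saccade RT out of range
    if reason is None and initial is not None and scored.rt_ms is not None:
        if scored.rt_ms < cfg.rt_min_ms or scored.rt_ms > cfg.rt_max_ms:
            reason = "rt_out_of_range"
    # rule 3: no initial saccade, or erroneous endpoint
    if reason is None:
        if initial is None:
            reason = "no_or_erroneous_initial_saccade"
        else:
            end = proc.saccade_endpoint(initial)
            d = np.hypot(*(ep.target_xy - end).T)
            if float(np.min(d)) > cfg.err_max_deg:
                reason = "no_or_erroneous_initial_saccade"
    scored.excluded = reason is not None
    scored.exclusion_reason = reason or "none"
    return scored


def score_run(
    proc: ProcessedRun,
    trials: list[TrialSpec],
    cfg: ScoreConfig | None = None,
    eccentricity_deg: float = 12.0,
) -> list[ScoredTrial]:
    """Label, score, and apply exclusions for every trial of one run."""
    cfg = cfg or ScoreConfig()
    epochs = epochs_from_trials(trials, eccentricity_deg)
    out = []
    for trial, ep in zip(trials, epochs):
        initial, final = label_saccades(proc, ep, cfg)
        idx, fallback = attribute_reported_target(trial, proc, ep, final)
        st = score_trial(trial, proc, ep, initial, final, idx, cfg, fallback)
        out.append(apply_exclusions(st, proc, ep, initial, cfg))
    return out


def scored_to_frame(scored: list[ScoredTrial], subject: int | str = 0) -> pd.DataFrame:
    """Stack ScoredTrials into the tabular form the statistics layer consumes."""
    df = pd.DataFrame([vars(s) for s in scored])
    df.insert(0, "subject", subject)
    return df
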