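import numpy as np
import pytest

from mgsaccade import (
    Fixation,
    GazeRun,
    ProcessedRun,
    Saccade,
    SimulationParams,
    TaskDesign,
    TrialSpec,
)
from mgsaccade.preprocess import EventSet, epochs_from_trials, preprocess_run
from mgsaccade.pipeline import simulate_subject


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free simulation: no jitter, drift, blinks, or pupil fluctuation."""
    return SimulationParams(
        fixation_jitter_sd_deg=0.0,
        drift_sd_deg=0.0,
        blink_rate_hz=0.0,
        pupil_fluct=0.0,
    )


@pytest.fixture(scope="session")
def one_run_design():
    return TaskDesign(n_runs=1)


@pytest.fixture(scope="session")
def quiet_subject(one_run_design, quiet_params):
    """One noise-free simulated run, preprocessed; shared across tests."""
    trials, reports, runs, truth = simulate_subject(
        one_run_design, quiet_params, seed=11
    )
    proc = preprocess_run(runs[0], epochs_from_trials(trials))
    return {"trials": trials, "reports": reports, "runs": runs,
            "truth": truth, "proc": proc}


def make_trial(
    condition="R1",
    angles=(0.0,),
    cued=0,
    t_start=0,
    iti=3000,
    colors=None,
):
    """TrialSpec with the standard epoch arithmetic."""
    cue = t_start + 4000
    fb = cue + 1500
    return TrialSpec(
        run_id=0,
        trial_id=0,
        condition=condition,
        target_angles_deg=tuple(angles),
        target_colors=tuple(colors or ("red", "blue")[: len(angles)]),
        cued_index=cued,
        iti_ms=iti,
        t_start=t_start,
        cue_onset=cue,
        feedback_onset=fb,
        t_end=fb + 800 + iti,
    )


def make_toy_proc(n, saccades, excursions=None):
    """Hand-built ProcessedRun: piecewise-linear x/y plus consistent events.

    ``saccades``: list of (onset_ms, dur_ms, end_xy). Positions ramp
    linearly during each movement and are constant elsewhere; fixations
    tile the remaining time. ``excursions``: list of (t0, t1, xy offset)
    applied after event construction (e.g., to break fixation without a
    saccade event).
    """
    x = np.zeros(n)
    y = np.zeros(n)
    evs = EventSet()
    cur = np.zeros(2)
    cursor = 0
    for onset, dur, end_xy in saccades:
        end_xy = np.asarray(end_xy, dtype=float)
        i0, i1 = int(onset), int(onset) + int(dur) - 1
        x[cursor:i0] = cur[0]
        y[cursor:i0] = cur[1]
        ramp = np.linspace(0.0, 1.0, i1 - i0 + 1)
        x[i0 : i1 + 1] = cur[0] + ramp * (end_xy[0] - cur[0])
        y[i0 : i1 + 1] = cur[1] + ramp * (end_xy[1] - cur[1])
        evs.saccades.append(
            Saccade(
                i_on=i0, i_off=i1, onset_ms=i0, offset_ms=i1,
                amplitude_deg=float(np.hypot(*(end_xy - cur))),
                peak_velocity_deg_s=500.0,
            )
        )
        if i0 > cursor:
            evs.fixations.append(Fixation(cursor, i0 - 1, cursor, i0 - 1))
        cursor = i1 + 1
        cur = end_xy
    x[cursor:] = cur[0]
    y[cursor:] = cur[1]
    if cursor < n:
        evs.fixations.append(Fixation(cursor, n - 1, cursor, n - 1))
    for t0, t1, (dx, dy) in excursions or []:
        x[t0:t1] += dx
        y[t0:t1] += dy
    return ProcessedRun(
        run_id=0,
        t_ms=np.arange(n, dtype=np.int64),
        x=x, y=y,
        pupil=np.full(n, 1000.0),
        valid=np.ones(n, dtype=bool),
        speed=np.zeros(n),
        events=evs,
    )
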