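"""Task design for the memory-guided saccade experiment.

Three interleaved conditions are tested within every run:

* ``R1`` — remember one location, report it after the delay.
* ``R2-random`` — remember two locations, report the one cued by color.
* ``R2-best`` — remember two locations, report the one judged
  best-remembered (the cue is uninformative).

Targets are small dots placed on an invisible ring 12 degrees of visual
angle (dva) from fixation; on two-target trials the dots are separated by
at least 30 degrees of polar angle. Each trial steps through a fixed epoch
sequence: targets (500 ms), memory delay (3.5 s), response window (1.5 s),
feedback (targets re-presented, 800 ms), then a uniform 2-4 s intertrial
interval. Coordinates use fixation as the origin, +x rightward, +y upward,
polar angle counterclockwise from +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONDITIONS",
    "TaskDesign",
    "TrialSpec",
    "InvalidDesignError",
    "generate_design",
    "runs_needed",
    "circular_separation_deg",
    "polar_to_xy",
]

CONDITIONS = ("R1", "R2-random", "R2-best")

DEFAULT_COLORS = ("red", "yellow", "blue", "purple")


class InvalidDesignError(ValueError):
    """Raised when a TaskDesign cannot produce valid trials."""


def polar_to_xy(eccentricity_deg: float, angle_deg: float) -> tuple[float, float]:
    """Cartesian (x, y) in dva for a point at the given eccentricity/polar angle."""
    a = math.radians(angle_deg)
    return (eccentricity_deg * math.cos(a), eccentricity_deg * math.sin(a))


def circular_separation_deg(a_deg: float, b_deg: float) -> float:
    """Absolute circular distance between two polar angles, in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of the experiment.

    Defaults reproduce the study conditions: 30-trial runs with 10 trials
    per condition, targets on a 12 dva ring separated by >= 30 deg polar
    angle, and the 500/3500/1500/800 ms epoch sequence at 1000 Hz.
    """

    n_runs: int = 1
    trials_per_condition_per_run: int = 10
    eccentricity_deg: float = 12.0
    min_separation_deg: float = 30.0
    dot_radius_deg: float = 0.65
    target_ms: int = 500
    delay_ms: int = 3500
    response_ms: int = 1500
    feedback_ms: int = 800
    iti_range_ms: tuple[int, int] = (2000, 4000)
    colors: tuple[str, ...] = DEFAULT_COLORS
    sample_rate_hz: int = 1000
    lead_in_ms: int = 1000

    @property
    def trials_per_run(self) -> int:
        return 3 * self.trials_per_condition_per_run

    def validate(self) -> None:
        if self.n_runs < 1 or self.trials_per_condition_per_run < 1:
            raise InvalidDesignError("need at least one run and one trial per condition")
        if not (0.0 < self.min_separation_deg <= 180.0):
            raise InvalidDesignError(
                f"min_separation_deg must be in (0, 180], got {self.min_separation_deg}"
            )
        for name in ("target_ms", "delay_ms", "response_ms", "feedback_ms", "lead_in_ms"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be > 0")
        lo, hi = self.iti_range_ms
        if not (0 < lo <= hi):
            raise InvalidDesignError(f"invalid iti_range_ms {self.iti_range_ms}")
        if len(self.colors) < 2:
            raise InvalidDesignError("need at least two target colors")
        if self.eccentricity_deg <= 0:
            raise InvalidDesignError("eccentricity_deg must be > 0")
        if self.sample_rate_hz != 1000:
            raise InvalidDesignError("only 1000 Hz sampling is supported")


@dataclass(frozen=True)
class TrialSpec:
    """One trial: condition, target geometry, and epoch onsets within the run.

    ``epoch onsets`` are in run time (ms).  ``t_start`` is target onset;
    ``t_end`` is the end of the intertrial interval (= next trial's start).
    ``cued_index`` indexes ``target_angles_deg`` for R1/R2-random trials and
    is None on R2-best trials, where the report target is the subject's own
    choice.
    """

    run_id: int
    trial_id: int
    condition: str
    target_angles_deg: tuple[float, ...]
    target_colors: tuple[str, ...]
    cued_index: int | None
    iti_ms: int
    t_start: int
    cue_onset: int
    feedback_onset: int
    t_end: int

    @property
    def n_targets(self) -> int:
        return len(self.target_angles_deg)

    def target_xy(self, eccentricity_deg: float = 12.0) -> np.ndarray:
        """(n_targets, 2) array of Cartesian target positions in dva."""
        return np.array(
            [polar_to_xy(eccentricity_deg, a) for a in self.target_angles_deg]
        )


def _draw_angles(rng: np.random.Generator, n: int, min_sep: float) -> tuple[float, ...]:
    """Uniform angles on the circle subject to the pairwise separation floor."""
    first = float(rng.uniform(0.0, 360.0))
    if n == 1:
        return (first,)
    # Rejection sampling; acceptance probability (360 - 2*sep)/360 for sep<180.
    for _ in range(10_000):
        second = float(rng.uniform(0.0, 360.0))
        if circular_separation_deg(first, second) >= min_sep:
            return (first, second)
    raise InvalidDesignError(
        f"could not place two targets >= {min_sep} deg apart"
    )


def generate_design(design: TaskDesign, seed: int | np.random.Generator) -> list[TrialSpec]:
    """Generate the randomly interleaved trial list for all runs.

    Each run contains exactly ``trials_per_condition_per_run`` trials of each
    condition in shuffled order. Target polar angles are uniform on the
    circle subject to the separation constraint; two-target colors are drawn
    without replacement from the design's color set.
    """
    design.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    trials: list[TrialSpec] = []
    epoch = design.target_ms + design.delay_ms + design.response_ms + design.feedback_ms
    for run_id in range(design.n_runs):
        conds = np.repeat(np.arange(3), design.trials_per_condition_per_run)
        rng.shuffle(conds)
        t = design.lead_in_ms
        for trial_id, ci in enumerate(conds):
            cond = CONDITIONS[ci]
            n_targets = 1 if cond == "R1" else 2
            angles = _draw_angles(rng, n_targets, design.min_separation_deg)
            colors = tuple(rng.choice(design.colors, size=n_targets, replace=False))
            if cond == "R1":
                cued = 0
            elif cond == "R2-random":
                cued = int(rng.integers(0, 2))
            else:
                cued = None
            iti = int(rng.integers(design.iti_range_ms[0], design.iti_range_ms[1] + 1))
            cue_onset = t + design.target_ms + design.delay_ms
            feedback_onset = cue_onset + design.response_ms
            trials.append(
                TrialSpec(
                    run_id=run_id,
                    trial_id=trial_id,
                    condition=cond,
                    target_angles_deg=angles,
                    target_colors=colors,
                    cued_index=cued,
                    iti_ms=iti,
                    t_start=t,
                    cue_onset=cue_onset,
                    feedback_onset=feedback_onset,
                    t_end=t + epoch + iti,
                )
            )
            t += epoch + iti
    return trials


def runs_needed(trials_per_condition_goal: int, trials_per_condition_per_run: int = 10) -> int:
    """Minimum number of runs to reach a per-condition trial-count goal."""
    if trials_per_condition_goal <= 0 or trials_per_condition_per_run <= 0:
        raise ValueError("counts must be positive")
    return -(-trials_per_condition_goal // trials_per_condition_per_run)
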