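"""Sample-level gaze container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GazeRun"]


@dataclass
class GazeRun:
    """Monocular gaze samples for one run at 1000 Hz.

    ``t_ms`` is run time in milliseconds (uniform 1-ms spacing), ``x``/``y``
    are gaze position in degrees of visual angle with fixation at the
    origin, ``pupil`` is pupil size in arbitrary tracker units (0 during
    blinks).
    """

    run_id: int
    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.pupil) == n):
            raise ValueError("t_ms, x, y, pupil must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    def copy(self) -> "GazeRun":
        return GazeRun(
            self.run_id,
            self.t_ms.copy(),
            self.x.copy(),
            self.y.copy(),
            self.pupil.copy(),
        )
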