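"""Adapter stubs for externally deposited datasets.

The pipeline consumes the internal schema only (gaze TSV per run +
trial-table CSV; see :mod:`mgsaccade.io`). Published memory-guided
saccade datasets (e.g., EyeLink recordings shared as converted sample
tables) can be mapped onto that schema with a small amount of glue:

1. Export each run's samples as columns (time, x, y, pupil). Convert
   screen pixels to degrees of visual angle with fixation at the origin
   (+x rightward, +y upward) and resample/verify 1000-Hz spacing.
2. Write one ``gaze_runNN.tsv`` per run via :func:`mgsaccade.io.write_gaze`.
3. Build the trial table from the session log: condition, target polar
   angles (ring eccentricity), cued color index, and epoch onsets in run
   time, then :func:`mgsaccade.io.write_trials`.

``convert_samples`` below documents the expected mapping for a generic
long-format sample table. It is a convenience shim, untested against any
particular deposit, and deliberately free of download logic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gaze import GazeRun

__all__ = ["convert_samples"]


def convert_samples(
    df: pd.DataFrame,
    run_id: int = 0,
    time_col: str = "time",
    x_col: str = "x",
    y_col: str = "y",
    pupil_col: str = "pupil",
    pix_per_deg: float | None = None,
    center_xy: tuple[float, float] = (0.0, 0.0),
    flip_y: bool = False,
) -> GazeRun:
    """Map a long-format sample table onto a :class:`GazeRun`.

    ``pix_per_deg`` converts pixel coordinates to degrees after removing
    ``center_xy`` (the fixation point in source units); ``flip_y``
    accommodates screen coordinates with +y downward.
    """
    t = df[time_col].to_numpy()
    t = (t - t[0]).astype(np.int64)
    x = df[x_col].to_numpy(float) - center_xy[0]
    y = df[y_col].to_numpy(float) - center_xy[1]
    if pix_per_deg is not None:
        x = x / pix_per_deg
        y = y / pix_per_deg
    if flip_y:
        y = -y
    return GazeRun(run_id, t, x, y, df[pupil_col].to_numpy(float))
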