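"""File formats: gaze TSV, trial/scored CSV, YAML configs, JSON reports.

Gaze samples are tab-separated with header ``t_ms  x_deg  y_deg  pupil``,
one file per run. Trial tables and scored tables are CSV with one row
per trial. Configurations round-trip through YAML; statistics reports
are written as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TaskDesign, TrialSpec
from .gaze import GazeRun
from .preprocess import PreprocConfig
from .scoring import ScoreConfig
from .simulate import SimulationParams

__all__ = [
    "GazeFormatError",
    "write_gaze", "read_gaze",
    "write_trials", "read_trials",
    "write_report", "read_report",
    "PipelineConfig", "load_config", "dump_config",
]

GAZE_COLUMNS = ["t_ms", "x_deg", "y_deg", "pupil"]


class GazeFormatError(ValueError):
    """Malformed or inconsistent gaze sample file."""


def write_gaze(run: GazeRun, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "t_ms": run.t_ms, "x_deg": run.x, "y_deg": run.y, "pupil": run.pupil,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_gaze(path: str | Path, run_id: int | None = None) -> GazeRun:
    """Parse a gaze TSV, validating header, numeric rows, and 1-ms spacing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != GAZE_COLUMNS:
        raise GazeFormatError(
            f"{path}: expected header {GAZE_COLUMNS}, got {header} (line 1)"
        )
    try:
        df = pd.read_csv(path, sep="\t", dtype=float, float_precision="round_trip")
    except ValueError as exc:
        raise GazeFormatError(f"{path}: unparseable numeric data ({exc})") from exc
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise GazeFormatError(f"{path}: malformed row at line {line}")
    t = df["t_ms"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise GazeFormatError(f"{path}: non-monotone timestamps near line {line}")
    if np.any(dt != 1):
        raise GazeFormatError(f"{path}: sampling interval must be 1 ms")
    if run_id is None:
        stem = path.stem
        run_id = int(stem.rsplit("run", 1)[-1]) if "run" in stem else 0
    return GazeRun(
        run_id=run_id,
        t_ms=t.astype(np.int64),
        x=df["x_deg"].to_numpy(),
        y=df["y_deg"].to_numpy(),
        pupil=df["pupil"].to_numpy(),
    )


def write_trials(trials: list[TrialSpec], path: str | Path) -> Path:
    rows = []
    for tr in trials:
        rows.append({
            "run_id": tr.run_id, "trial_id": tr.trial_id,
            "condition": tr.condition,
            "target_angle_0": tr.target_angles_deg[0],
            "target_angle_1": (
                tr.target_angles_deg[1] if tr.n_targets > 1 else np.nan
            ),
            "color_0": tr.target_colors[0],
            "color_1": tr.target_colors[1] if tr.n_targets > 1 else "",
            "cued_index": -1 if tr.cued_index is None else tr.cued_index,
            "iti_ms": tr.iti_ms, "t_start": tr.t_start,
            "cue_onset": tr.cue_onset, "feedback_onset": tr.feedback_onset,
            "t_end": tr.t_end,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_trials(path: str | Path) -> list[TrialSpec]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        two = not pd.isna(r["target_angle_1"])
        out.append(TrialSpec(
            run_id=int(r["run_id"]), trial_id=int(r["trial_id"]),
            condition=str(r["condition"]),
            target_angles_deg=(
                (float(r["target_angle_0"]), float(r["target_angle_1"]))
                if two else (float(r["target_angle_0"]),)
            ),
            target_colors=(
                (str(r["color_0"]), str(r["color_1"]))
                if two else (str(r["color_0"]),)
            ),
            cued_index=None if int(r["cued_index"]) < 0 else int(r["cued_index"]),
            iti_ms=int(r["iti_ms"]), t_start=int(r["t_start"]),
            cue_onset=int(r["cue_onset"]),
            feedback_onset=int(r["feedback_onset"]), t_end=int(r["t_end"]),
        ))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return {float("inf"): "inf", float("-inf"): "-inf"}.get(obj, "nan")
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "design": TaskDesign,
    "simulation": SimulationParams,
    "preprocess": PreprocConfig,
    "scoring": ScoreConfig,
}


@dataclasses.dataclass
class PipelineConfig:
    """Nested configuration for the end-to-end pipeline."""

    design: TaskDesign = dataclasses.field(default_factory=TaskDesign)
    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    preprocess: PreprocConfig = dataclasses.field(default_factory=PreprocConfig)
    scoring: ScoreConfig = dataclasses.field(default_factory=ScoreConfig)
    n_subjects: int = 1
    seed: int = 0
    n_bins: int = 12
    bin_error_source: str = "R1"
    sensitivity_cutoff: float = 0.20


def _build_section(cls, data: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Build a PipelineConfig from YAML (path or text) or a dict.

    Unknown keys anywhere raise; omitted sections take their defaults.
    """
    if isinstance(source, dict):
        data = source
    else:
        try:
            is_file = Path(source).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        data = yaml.safe_load(text) or {}
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {}, name)
    for name in top_fields - set(_SECTION_TYPES):
        if name in data:
            kwargs[name] = data[name]
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path | None = None) -> str:
    data = dataclasses.asdict(cfg)
    text = yaml.safe_dump(_jsonable(data), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
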