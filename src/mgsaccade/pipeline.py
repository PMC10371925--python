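"""End-to-end orchestration: simulate -> preprocess -> score -> analyze."""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .design import TaskDesign, TrialSpec, generate_design
from .gaze import GazeRun
from .preprocess import PreprocConfig, epochs_from_trials, preprocess_run
from .scoring import ScoreConfig, score_run, scored_to_frame
from .simulate import ReportDraw, SimTruth, SimulationParams, simulate_gaze, simulate_memory_report
from .stats import analyze, sensitivity_rerun

__all__ = [
    "simulate_subject",
    "process_subject",
    "run_subject",
    "run_cohort",
    "run_pipeline",
]

log = logging.getLogger("mgsaccade")


def simulate_subject(
    design: TaskDesign,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> tuple[list[TrialSpec], list[ReportDraw], list[GazeRun], SimTruth]:
    """Design, memory reports, and gaze recordings for one subject."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = generate_design(design, rng)
    reports = [
        simulate_memory_report(tr, params, rng, design.eccentricity_deg)
        for tr in trials
    ]
    runs, truth = simulate_gaze(trials, reports, params, rng, design.eccentricity_deg)
    return trials, reports, runs, truth


def process_subject(
    runs: list[GazeRun],
    trials: list[TrialSpec],
    pre_cfg: PreprocConfig | None = None,
    score_cfg: ScoreConfig | None = None,
    subject: int | str = 0,
    eccentricity_deg: float = 12.0,
    return_procs: bool = False,
):
    """Preprocess and score all runs of one subject -> scored-trial table."""
    pre_cfg = pre_cfg or PreprocConfig()
    score_cfg = score_cfg or ScoreConfig()
    frames, procs = [], []
    for run in runs:
        run_trials = [t for t in trials if t.run_id == run.run_id]
        epochs = epochs_from_trials(run_trials, eccentricity_deg)
        proc = preprocess_run(run, epochs, pre_cfg)
        scored = score_run(proc, run_trials, score_cfg, eccentricity_deg)
        for s in scored:
            if s.excluded:
                log.info(
                    "excluded subject=%s run=%d trial=%d reason=%s",
                    subject, s.run_id, s.trial_id, s.exclusion_reason,
                )
        frames.append(scored_to_frame(scored, subject))
        procs.append(proc)
    table = pd.concat(frames, ignore_index=True)
    return (table, procs) if return_procs else table


def run_subject(
    design: TaskDesign,
    params: SimulationParams,
    seed: int | np.random.Generator,
    pre_cfg: PreprocConfig | None = None,
    score_cfg: ScoreConfig | None = None,
    subject: int | str = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one subject and push them through preprocessing and scoring."""
    trials, _, runs, truth = simulate_subject(design, params, seed)
    table = process_subject(
        runs, trials, pre_cfg, score_cfg, subject, design.eccentricity_deg
    )
    return table, truth


def run_cohort(
    n_subjects: int,
    design: TaskDesign,
    params: SimulationParams,
    seed: int,
    pre_cfg: PreprocConfig | None = None,
    score_cfg: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Full-pipeline scored table for a simulated cohort (one row per trial)."""
    ss = np.random.SeedSequence(seed)
    tables = []
    for subj, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        table, _ = run_subject(design, params, rng, pre_cfg, score_cfg, subject=subj)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def run_pipeline(config: mio.PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages and write artifacts under ``outdir``.

    Per subject: trial table, per-run gaze TSVs, scored CSV, QC JSON;
    plus the cohort statistics report (``report.json``) and the
    sensitivity rerun. Fixed seed => identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: preprocess=%s scoring=%s",
             asdict(config.preprocess), asdict(config.scoring))
    ss = np.random.SeedSequence(config.seed)
    tables = []
    for subj, child in enumerate(ss.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        sdir = outdir / f"sub{subj:03d}"
        sdir.mkdir(exist_ok=True)
        try:
            trials, _, runs, truth = simulate_subject(
                config.design, config.simulation, rng
            )
            mio.write_trials(trials, sdir / "trials.csv")
            for run in runs:
                mio.write_gaze(run, sdir / f"gaze_run{run.run_id:02d}.tsv")
            truth.trials.to_csv(sdir / "sim_truth.csv", index=False)
            table, procs = process_subject(
                runs, trials, config.preprocess, config.scoring,
                subject=subj, eccentricity_deg=config.design.eccentricity_deg,
                return_procs=True,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for subject {subj}: {exc}") from exc
        table.to_csv(sdir / "scored.csv", index=False)
        qc = {
            "subject": subj,
            "runs": [
                {
                    "run_id": p.run_id,
                    "n_blinks": len(p.events.blinks),
                    "n_saccades": len(p.events.saccades),
                    "recal": None if p.recal is None else asdict(p.recal),
                    "flags": p.flags,
                }
                for p in procs
            ],
            "exclusions": table[table["excluded"]][
                ["run_id", "trial_id", "exclusion_reason"]
            ].to_dict(orient="records"),
        }
        mio.write_report(qc, sdir / "qc.json")
        tables.append(table)
    scored = pd.concat(tables, ignore_index=True)
    scored.to_csv(outdir / "scored_all.csv", index=False)
    report = analyze(
        scored, n_bins=config.n_bins, bin_error_source=config.bin_error_source
    )
    try:
        report["sensitivity"] = sensitivity_rerun(
            scored, config.sensitivity_cutoff,
            n_bins=config.n_bins, bin_error_source=config.bin_error_source,
        )
    except ValueError as exc:
        report["sensitivity"] = {"error": str(exc)}
    mio.write_report(report, outdir / "report.json")
    return report
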