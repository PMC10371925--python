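# mgsaccade

Analysis pipeline for **memory-guided saccade** experiments on spatial
working memory, plus a synthetic experiment simulator that makes every
stage of the pipeline verifiable without eye-tracking hardware.

The task it models: a participant fixates centrally while one or two
colored dots flash on an invisible ring 12° from fixation, remembers the
location(s) over a 3.5-s delay, and reports one location with a saccade.
Three conditions are interleaved — remember one item (**R1**), remember
two and report a randomly cued one (**R2-random**), or remember two and
report the one judged best-remembered (**R2-best**). The scientific
question is whether people can introspect the *relative* quality of
multiple spatial memories: if they can, recall error should drop (and
decision time rise) on R2-best relative to R2-random trials.

## What the package does

- **`mgsaccade.design` / `mgsaccade.simulate`** — task-design generation
  (condition mix, ring geometry, ≥30° polar separation, epoch timing) and
  a two-layer generative model: a *variable-precision* memory layer
  (per item and trial, precision J ~ Gamma; report noise sd = 1/√J; the
  R2-best chooser picks the item with the smaller drawn sd, with lapses)
  and an oculomotor layer producing 1000-Hz gaze traces with
  main-sequence saccades, fixational jitter, blinks, per-trial drift, and
  a per-run cubic miscalibration warp. Full ground truth is returned.
- **`mgsaccade.preprocess`** — condition-blind gaze preprocessing:
  blink masking (pupil below the run-wise 1.5th percentile, ±200 ms),
  Gaussian smoothing (5-ms SD) and central-difference velocity,
  saccade/fixation segmentation (30°/s velocity, 0.0075-s duration,
  0.25° amplitude thresholds, with dual-threshold onset/offset
  refinement), per-trial drift correction on the pre-cue fixation, and
  per-run cubic recalibration fit from feedback-epoch fixations within
  2.5° of a target.
- **`mgsaccade.scoring`** — labels the initial (>5°, <150 ms) and final
  response saccades, computes RT (cue → initial-saccade onset) and recall
  error (final endpoint → reported target, Euclidean), attributes the
  reported target on R2-best trials from the feedback fixation, and
  applies the three blinded exclusion rules (fixation break > 2.5°;
  RT < 100 ms or > 1 s; no initial saccade or endpoint > 5° from every
  target).
- **`mgsaccade.stats`** — subject × condition summaries, one-way
  repeated-measures ANOVA (F = MS_cond / MS_cond×subj, partial η²),
  paired t with Cohen's d_z, tangential endpoint precision (SD of the
  endpoint component orthogonal to the fixation–target axis), the 12-bin
  location-heuristic analysis with a group Fisher r-to-z test, inclusion
  -rate contrasts, the noncentral-t power calculator, and a sensitivity
  rerun that drops high-exclusion subjects.
- **`mgsaccade.io` / `mgsaccade.pipeline` / `mgs` CLI** — gaze TSV and
  trial/scored CSV formats, YAML configs, JSON reports, and the
  end-to-end `simulate → preprocess → score → analyze` orchestration.

## Worked example

Short narrative scripts live in `examples/`. Simulating a 20-subject
cohort at the study scale (~200 trials/condition) and running the
inferential layer (`examples/04_condition_statistics.py`):

```
recall error: R1=0.995, R2-random=1.617, R2-best=1.349
rm-ANOVA: F(2, 38) = 353.86, p = 2.7e-25, partial eta^2 = 0.95
R2-random vs R2-best: t(19) = 9.49, p = 1.2e-08, dz = 2.12
tangential SD (deg): R1=0.847, R2-random=1.356, R2-best=1.102
sample size for dz = 0.70 at 80% power: n = 19
```

Reading the numbers: recall error is lowest with one item (R1), worst
when one of two items is randomly probed (R2-random), and reliably
improves when the participant chooses the best-remembered item
(R2-best) — the positive t on the critical R2-random vs R2-best contrast
is the choice benefit. The same ordering holds for tangential SD, the
variability-based precision measure. The power line reproduces the
design calculation: detecting d_z = 0.70 at 80% power with a two-tailed
paired t test needs 19 subjects.

`examples/05_location_heuristic.py` contrasts a chooser that introspects
trial-by-trial precision with one that always reports targets in its
"good" screen region; only the latter produces a reliably negative
correlation between per-bin R1 recall error and per-bin R2-best choice
probability:

```
precision chooser  : mean r = +0.060, group t(19) = +0.86, p = 0.402, dz = +0.19
location heuristic : mean r = -0.826, group t(19) = -23.61, p = 1.53e-15, dz = -5.28
```

The full pipeline is also available from the shell:

```bash
mgs run --out out/ --seed 7 --subjects 20
mgs simulate --out sim/ --seed 1
mgs score --gaze sim/ --trials sim/trials.csv --out scored.csv
mgs analyze --scored scored.csv --out report.json
```

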