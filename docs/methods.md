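# Methods

This note documents the models and procedures implemented in
`mgsaccade`, the parameter choices that matter, and what the synthetic
data do and do not establish about real recordings.

## Task and coordinate conventions

Trials step through a fixed epoch sequence: targets 500 ms, delay
3500 ms, response 1500 ms, feedback (targets re-presented) 800 ms, then
a uniform 2–4 s intertrial interval; runs hold 30 trials, 10 per
condition (R1, R2-random, R2-best), randomly interleaved. Targets sit on
a ring 12 degrees of visual angle (dva) from fixation; two-target trials
enforce ≥ 30° circular polar separation (rejection sampling; the
constraint is infeasible only above 180°, which the design validator
rejects). Gaze coordinates put fixation at the origin, +x rightward,
+y upward, polar angle counterclockwise from +x; all positions are in
dva and time is in ms at 1000 Hz.

## Generative model (synthetic_data)

**Memory layer.** Each item on each trial receives an encoding precision
J drawn from Gamma(shape k, scale θ), and its report noise is an
isotropic Gaussian with sd = 1/√J. The scale is set per condition-role so
that E[sd] equals the configured value, using
E[J^(−1/2)] = θ^(−1/2)·Γ(k−½)/Γ(k); defaults are E[sd] = 0.8° for the R1
item and 1.3° per item on two-item trials (the set-size effect), with
k = 3 (substantial trial-to-trial fluctuation; k must exceed ½ for the
mean to exist). The R2-best chooser ranks items by their *drawn* sd —
introspection of representation quality, not oracle access to the
realized error — and lapses to a random item with probability 0.1 by
default. Two alternative choosers exist for analysis-validation studies:
`random` (uninformed) and `location`, which ignores the trial's draws
and picks the item in the subject's better screen region. Spatial
inhomogeneity is a smooth polar modulation of mean sd,
1 + a·cos(angle − phase), default a = 0 (homogeneous).

The form of the error distribution (Gaussian per item with
gamma-fluctuating precision, no explicit guess/swap mixture) is a
modeling choice; heavier-tailed behavior emerges from the precision
fluctuation itself, and the effective tail weight is controlled by k.

**Oculomotor layer.** Saccades follow a normalized logistic position
profile with duration 2.2 ms/deg × amplitude + 21 ms and steepness
c = 9, which yields main-sequence-plausible peak velocities (~490°/s at
12°). Response latencies are Gaussian per condition (means 300/380/480 ms
for R1/R2-random/R2-best, sd 80 ms, clipped to [120, 1400] ms), with a
3% lapse probability adding 250–600 ms. The primary saccade lands at
gain 0.9 of the report vector when a corrective saccade follows
(probability 0.7), otherwise exactly at the report location; the
corrective saccade lands exactly. During feedback the eye saccades to
the *true* location of the reported target (the re-presented dot) —
this is what makes per-run recalibration identifiable. Two-percent of
trials contain a brief 3–5° fixation-break excursion during the delay,
exercising exclusion rule 1. Fixational jitter is white Gaussian noise
(sd 0.05°), per-trial drift is a constant offset (sd 0.3° per axis),
blinks are pupil dropouts (Poisson 0.1 Hz, 80–120 ms), and the pupil
otherwise fluctuates slowly (two incommensurate sinusoids + noise) so
that the sub-percentile tail of a blink-free run clusters into a few
dips rather than scattering isolated samples. When `pupil_fluct = 0`
and `blink_rate_hz = 0` the pupil is constant, and the strict-below
percentile rule correctly yields zero blinks. Finally each run's
samples pass through a per-channel cubic warp x′ = P₃(x), y′ = P₃(y)
(identity by default).

All randomness flows from one `numpy` Generator; identical
(design, params, seed) produce bit-identical runs and ground truth. The
ground truth records per-trial drawn sds, the reported item and
location, nominal saccade onsets, drift offsets, warp coefficients, and
a log of *every* injected movement (primary, corrective, feedback,
return, break), which is what detector-recovery tests compare against.

## Preprocessing

Order: blink masking → smoothing/velocity → segmentation → per-trial
drift correction → per-run recalibration. No stage sees the condition
label; the interface type (`TrialEpochs`) carries only epoch times and
target geometry.

- **Blinks:** samples with pupil strictly below the run-wise 1.5th
  percentile (linear-interpolation quantile), dilated by ±200 ms;
  intervals are clipped to the run and downstream computation never
  crosses them (no interpolation — each valid segment is processed
  independently). A run left with no valid samples raises.
- **Smoothing/velocity:** Gaussian kernel, 5-ms SD, truncated at 4 SD
  and renormalized near edges (convolution of the data and of a ones
  vector, ratio taken); velocity is the central difference of the
  smoothed traces × 1000 (deg/s); speed its Euclidean norm. Uniform
  1-ms sampling is enforced.
- **Saccades:** the *core* of an event is a maximal run of speed ≥
  30 deg/s. Its extent is then refined outward sample by sample while
  speed decreases monotonically, down to an adaptive low threshold
  max(30/3, 8% of the event's peak speed). The duration (≥ 0.0075 s,
  counted as refined samples × 1 ms) and displacement (≥ 0.25°,
  measured between positions 8 ms outside the refined extent) gates are
  applied to the refined event. Rationale: with a 5-ms smoothing kernel
  the supra-30°/s interval of a small saccade is bounded by its
  amplitude/threshold area (≤ ~7.6 ms at 0.5°, for any velocity
  profile), so a detector whose extent is the bare supra-threshold run
  cannot recover 0.5° saccades at all and reports onsets several ms
  late below ~2°; the dual-threshold refinement — standard practice in
  velocity-based event detection — recovers every ≥ 0.5° saccade on
  noise-free traces with ≤ 2 ms onset error while leaving large-saccade
  onsets unchanged, and produces zero false alarms on fixational jitter
  of sd ≤ 0.05°. Fixations tile the remaining valid time; their
  centroids and saccade endpoints are always read from the *current*
  (corrected) traces. Endpoints are read from the post-saccadic
  fixation (mean of ≤ 100 ms, skipping an 8-ms settle window).
- **Drift correction:** per trial, the centroid of the longest fixation
  overlapping [trial start, cue onset) — a duration-weighted proxy for
  the modal fixation position — is subtracted from the trial's samples.
  Trials without a pre-cue fixation are flagged and left uncorrected.
  The operation is idempotent.
- **Recalibration:** per trial, the feedback-epoch fixation nearest a
  target (ties → lower index; ≥ 50 ms overlap; head-settle skipped) is
  paired with that target's true position; pairs farther than 2.5° are
  discarded. With ≥ 8 pairs (twice the 4 coefficients per coordinate)
  one cubic per coordinate is fit measured → true by least squares and
  applied to the whole run. No cross-terms: the warp model is
  per-coordinate, matching the simulator's warp; cross-coupled
  distortions are outside the model class. A fit that is
  ill-conditioned or fails to improve the mean pair distance (beyond a
  1e-6 float tolerance) is discarded and flagged, so recalibration can
  only improve or preserve feedback-fixation accuracy. Note that a pure
  constant offset is already absorbed by drift correction, in which
  case the recalibration correctly declines to act.

## Scoring and exclusion

Initial saccade: first saccade at/after the cue with amplitude > 5° and
duration < 150 ms. Final saccade: last saccade with offset before
feedback onset (equal to the initial one when no corrective saccade
occurred). RT = initial onset − cue onset; recall error = Euclidean
distance from the final endpoint to the reported target's true
location; n_saccades counts every detected saccade in [cue, feedback),
with no extra amplitude floor. R2-best attribution uses the same
feedback-fixation selection as recalibration, falling back (flagged) to
the target nearest the final endpoint. Exclusion rules fire in order:
(1) any valid drift-corrected sample beyond 2.5° eccentricity during
[target onset, cue onset); (2) RT < 100 ms or > 1000 ms (bounds
inclusive of the valid range); (3) no qualifying initial saccade —
amplitude and duration gates both applied, consistent with the initial-
saccade definition — or an initial endpoint > 5° from every target.
The first firing rule is recorded; the decision never reads the
condition label beyond target geometry.

## Statistics

The rm-ANOVA is the explicit two-way decomposition SS_total =
SS_subject + SS_condition + SS_error with the condition × subject
interaction as error: F = MS_cond/MS_error, df = (k−1, (k−1)(n−1)),
partial η² = SS_cond/(SS_cond + SS_error), p from the F distribution.
No sphericity correction is applied (matching integer error dfs);
perfectly additive or constant matrices are flagged degenerate rather
than returning spurious statistics. Paired t: t = mean(d)/(sd(d)/√n),
two-tailed, d_z = mean(d)/sd(d); zero-variance differences are flagged,
with t = 0 for identical vectors. Tangential precision rotates each
endpoint by −(target polar angle) and returns the sample SD (ddof 1) of
the rotated y. The 12-bin heuristic analysis uses 30° bins anchored at
0° (rightward); per subject it correlates (Pearson by default, Spearman
optional) the mean recall error of included error-source trials per bin
with the proportion of included R2-best trials reporting a target in
that bin; bins lacking either an error-source trial or an available
R2-best target are excluded pairwise (never zero-filled — a zero would
fabricate a choice probability where no target appeared); subjects with
< 3 usable bins or zero variance are dropped with flags; |r| is capped
at 1 − 1e-12 before atanh; the group test is a two-tailed one-sample t
on the Fisher z values. Inclusion-rate contrasts are uncorrected
planned paired t tests. The power calculator scans n upward using the
exact noncentral-t power function (ncp = d_z√n, df = n − 1) and returns
the smallest n reaching the target power; d_z = 0.70, power 0.80,
α = 0.05 gives n = 19. The sensitivity rerun drops subjects whose
overall excluded-trial proportion exceeds the cutoff (default 0.20) and
repeats the full report.

## Validation strategy and problem sizes

The simulator is the oracle for the pipeline: detector recovery is
checked against the injected-saccade log on noise-free runs (amplitude
grid 0.5–12° plus two full simulated runs); recalibration against known
warps of ≤ 1° magnitude (mean feedback-fixation error < 0.3° after
correction, never worse than before); scoring RT against nominal
onsets (±2 ms). The statistics are cross-checked against independent
oracles (pingouin's rm-ANOVA, textbook paired-t formulas, statsmodels'
power solver) to 1e-10. Calibration studies run the memory layer
directly (vectorized), at the study scale of 20 subjects × 200
trials/condition: under identical condition parameters with an
uninformed chooser, the critical R2-random vs R2-best paired t rejects
at close to the nominal 5% rate over 200 replications; with the
precision-ranking chooser the error ordering R1 < R2-best < R2-random
appears in ≥ 95% of 100 cohorts, and the same ordering survives the
full gaze pipeline on smaller full-synthesis cohorts (20 subjects ×
30 trials). The heuristic analysis is validated by construction:
location-agnostic choosers leave the group Fisher-z test null,
location-heuristic choosers drive it reliably negative.

## What the synthetic data do not show

The simulator emulates the features the pipeline's contracts depend on
(epoch structure, main-sequence kinematics, blinks, drift, smooth
miscalibration, variable-precision errors) but not: binocular or
pupil-size physiology, saccadic curvature and dynamic overshoot,
head-movement or tracker-slip artifacts, non-stationary drift within a
trial, swap errors between memoranda, or strategic behavior beyond the
three implemented choosers. Passing tests therefore certify the
pipeline's internal logic and its behavior under this model class, not
performance on any particular hardware's noise profile. The per-
coordinate cubic recalibration cannot correct cross-coupled (x–y)
distortions; real sessions with such warps would retain residual error.

## Parameters at a glance

| Parameter | Default | Units | Role |
|---|---|---|---|
| memory_sd_mean_deg | R1: 0.8, R2: 1.3 | dva | mean report noise per condition-role |
| precision_shape | 3.0 | — | gamma shape of precision fluctuation |
| choice_lapse | 0.1 | prob | random-choice lapses on R2-best |
| rt_mean_ms | 300/380/480 | ms | latency per condition |
| fixation_jitter_sd_deg | 0.05 | dva | white fixational noise |
| drift_sd_deg | 0.3 | dva | per-trial constant drift |
| blink_rate_hz | 0.1 | 1/s | pupil-dropout rate |
| blink_percentile / pad | 1.5 / 200 | % / ms | blink masking |
| smooth_sd_ms | 5 | ms | Gaussian kernel SD |
| vel/dur/amp thresholds | 30 / 0.0075 / 0.25 | °/s, s, ° | saccade gates |
| refine_low_frac / floor_div | 0.08 / 3 | — | onset/offset refinement |
| init_min_amp / init_max_dur | 5 / 150 | ° / ms | initial-saccade gates |
| rt_min / rt_max | 100 / 1000 | ms | RT exclusion window |
| fixwin_deg / err_max_deg | 2.5 / 5 | ° | exclusion windows |
| recal order/gate/min points | 3 / 2.5 / 8 | — / ° / pairs | recalibration |
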