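"""Simulate one subject's session and look at the ground truth.

Builds a 2-run design (30 trials/run, 10 per condition), draws
variable-precision memory reports, and synthesizes 1000-Hz gaze traces.
"""

from collections import Counter

from mgsaccade import SimulationParams, TaskDesign
from mgsaccade.pipeline import simulate_subject

design = TaskDesign(n_runs=2)
params = SimulationParams()
trials, reports, runs, truth = simulate_subject(design, params, seed=1)

print(f"trials: {len(trials)}  conditions: {Counter(t.condition for t in trials)}")
print(f"runs: {len(runs)}; run 0 holds {runs[0].n_samples} samples "
      f"({runs[0].n_samples / 1000:.0f} s at 1000 Hz)")
print("\nfirst three trials of ground truth (reported item, true saccade onset):")
cols = ["run_id", "trial_id", "condition", "report_index", "rt_true_ms"]
print(truth.trials[cols].head(3).to_string(index=False))
print(f"\ninjected saccades logged: {len(truth.saccades)} "
      f"(labels: {Counter(truth.saccades['label'])})")
# The rt_true_ms column is the latency the scorer must recover; the
# saccade log is what the detector must find.
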