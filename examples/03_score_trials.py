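"""Score a simulated subject: RT, recall error, and blinded exclusions."""

from mgsaccade import TaskDesign, SimulationParams
from mgsaccade.pipeline import run_subject

table, truth = run_subject(TaskDesign(n_runs=8), SimulationParams(), seed=3)

inc = table[~table["excluded"]]
print("per-condition means over included trials:")
print(inc.groupby("condition")[["recall_error_deg", "rt_ms", "n_saccades"]]
      .mean().round(3).to_string())
print(f"\nexcluded {table['excluded'].sum()} of {len(table)} trials:")
print(table[table["excluded"]]["exclusion_reason"].value_counts().to_string())
# Expected pattern: lowest error and fastest RT on R1; R2-best error below
# R2-random (the best-item choice advantage); RT slowest on R2-best.
# Single subjects are noisy — cohort-level inference lives in example 04.
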