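"""Run the whole chain and classify population-years as source/sink/stable.

Simulates a reduced six-population, 28-year study, fits every vital-rate
model with AICc form selection, propagates uncertainty with a parametric
bootstrap (betas for probabilities, log-normals for count means), and
classifies each population-year by whether its 95% interval for the
per-capita metapopulation contribution C lies above 1 (source), below 1
(sink) or overlaps it (stable).
"""

from pathlib import Path

from sourcesink import CohortDesign
from sourcesink.pipeline import RunConfig, run_pipeline, summarize_contributions

cfg = RunConfig(
    out_dir=Path("scratch/example_run"), seed=11,
    cohorts=CohortDesign(nestlings=12, adults=3),   # reduced banding effort
    survival_forms=("null", "linear"), movement_forms=("null", "quadratic"),
    theta_forms=("null", "quadratic"), attempts_forms=("null",),
    nest_forms=("null",), fledged_forms=("null",),
    juv_interaction=False, n_starts=1, gtol=1e-5,
    nest_random_effects=False, n_reps=2000)

contrib = run_pipeline(cfg, force=True)
summary = summarize_contributions(contrib)

print(f"\nclassified {summary['n_population_years']} population-years "
      f"({summary['n_post_invasion']} post-invasion): "
      f"{summary['class_counts']}")
print(f"fraction of post-invasion years with C >= 1: "
      f"{summary['frac_C_ge_1']:.2f}")
print(f"mean years-since-invasion when C >= 1: "
      f"{summary['mean_tsi_C_ge_1']:.1f}   when C < 1: "
      f"{summary['mean_tsi_C_lt_1']:.1f}")
print("\nA population-year with C >= 1 replaces itself in the metapopulation")
print("(via retention, emigration and recruited offspring); the tsi contrast")
print("shows sources clustering early in the invasion and sinks late.")
print(f"\nfull tables in {cfg.out_dir}/ (contributions.csv, vital_rates.csv,")
print("model_ranking.csv, summary.txt, manifest.json)")
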