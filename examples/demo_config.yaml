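# Demo run configuration for the `sourcesink` CLI.
#
#   sourcesink pipeline --config examples/demo_config.yaml --out demo_run
#
# A reduced two-population, eight-year study that runs end to end in
# seconds.  Omitted fields take the package defaults (28-year six-population
# schedule, full candidate model sets, 10,000 bootstrap replicates).
out_dir: demo_run
seed: 5
n_reps: 1000
schedule:
  populations: [A, B]
  invasion_year: {A: 2002}
  study_years: [2000, 2007]
  available_from: {}
cohorts: {nestlings: 25, adults: 10}
survival_forms: ["null", linear]
movement_forms: ["null"]
theta_forms: ["null", quadratic]
attempts_forms: ["null"]
nest_forms: ["null"]
fledged_forms: ["null"]
juv_interaction: false
n_starts: 1
gtol: 1.0e-06
nest_random_effects: false
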