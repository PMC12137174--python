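# Reduced configuration for quick demonstration runs: 12 counties in 3
# states, 7 abridged age groups, years 2009-2012, 3 cause groups, and
# 5 models x 4 draws. The full default configuration (48 counties, 19 age
# groups, 11 years, 16 causes, 50 x 20 draws) is used when no config is
# given.
out_dir: results/small
seed: 3
synthetic:
  n_counties: 12
  n_states: 3
  n_races: 2
  n_causes: 3
  years: [2009, 2010, 2011, 2012]
  age_starts: [0.0, 1.0, 5.0, 15.0, 45.0, 65.0, 85.0]
observation:
  n_per_obs: 600
  aggregate_fraction: 0.25
n_models: 5
draws_per_model: 4
change_years: [2009, 2012]
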