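# Base-case inputs for the nationwide obstetric-training cost-utility model.
# All scalars are the published national base case (England, 2017 GBP).
# The `psa` section declares the sampling distribution for each uncertain
# parameter: triangular(min, mode, max) or beta(mean, sd) truncated to
# [lo, hi]; parameters absent here are held fixed in the PSA.
model:
  annual_births: 648107
  horizon_years: 30
  discount_rate: 0.035
  claims_inflation: 0.10
  baseline_obpi_prob: 0.000192
  cost_prompt_first: 16.91
  cost_prompt_subsequent: 15.56
  cost_sd_first: 1.79
  cost_sd_subsequent: 1.43
  mean_litigation_cost: 338879
  utility_affected_adult: 0.56
  utility_parent_affected: 0.80
  utility_population: 0.86
  adult_age: 18
  effect_anchor_years: [0, 4, 12]
  effect_anchor_probs: [0.000192, 0.000150, 0.0]
  qaly_discounting: true
  schedule_round_decimals: 6

# Births covered by established training at model start, by whole years
# of established training. Coverage is fixed throughout the horizon.
coverage:
  - {years_established: 1, births: 38077}
  - {years_established: 2, births: 18991}
  - {years_established: 3, births: 32269}
  - {years_established: 4, births: 23261}
  - {years_established: 5, births: 31111}
  - {years_established: 6, births: 45093}
  - {years_established: 7, births: 39944}
  - {years_established: 8, births: 8366}
  - {years_established: 15, births: 7386}

psa:
  annual_births: {kind: triangular, min: 611337, mode: 648107, max: 671255}
  # Range from alternative published incidence estimates; sd = half-range.
  baseline_obpi_prob: {kind: beta, mean: 0.000192, sd: 0.000055, lo: 0.0, hi: 1.0}
  # Costs varied +/-20% around the base case.
  cost_prompt_first: {kind: triangular, min: 13.53, mode: 16.91, max: 20.29}
  cost_prompt_subsequent: {kind: triangular, min: 12.45, mode: 15.56, max: 18.67}
  cost_sd_first: {kind: triangular, min: 1.43, mode: 1.79, max: 2.14}
  cost_sd_subsequent: {kind: triangular, min: 1.14, mode: 1.43, max: 1.71}
  mean_litigation_cost: {kind: triangular, min: 271103, mode: 338879, max: 406654}
  # Utility ranges are mean +/- one sd. The population-norm upper bound
  # is truncated at 1.00 (mean + sd exceeds it), so its sd is mean - min.
  utility_affected_adult: {kind: beta, mean: 0.56, sd: 0.28, lo: 0.0, hi: 1.0}
  utility_parent_affected: {kind: beta, mean: 0.80, sd: 0.19, lo: 0.0, hi: 1.0}
  utility_population: {kind: beta, mean: 0.86, sd: 0.24, lo: 0.0, hi: 1.0}
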