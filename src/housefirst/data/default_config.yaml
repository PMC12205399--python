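# Default parameter configuration: base-case values with uncertainty ranges.
# Each uncertain quantity is {base, low, high, family}; family is the sampling
# distribution used in the probabilistic sensitivity analysis (quantile-matched
# so that low/high are the 2.5th/97.5th percentiles, samples clipped to range).
# Quantities without a published range are {base, family: fixed}.
schema_version: 1

demographics:
  n_persons: 1000
  male_fraction: 0.70
  age_mean_male: 46.4
  age_sd_male: 14.0
  age_mean_female: 46.5
  age_sd_female: 14.3
  entry_age_min: 18
  entry_age_max: 89

mortality:
  # annual non-overdose excess mortality rates, per person per year
  excess_oud_out_housed:    {base: 0.0098, low: 0.0074, high: 0.0125, family: lognormal}
  excess_oud_out_unhoused:  {base: 0.0032, low: 0.0024, high: 0.0041, family: lognormal}
  excess_homeless_out:      {base: 0.0128, low: 0.0065, high: 0.0203, family: lognormal}
  excess_homeless_in:       {base: 0.0055, low: 0.0028, high: 0.0084, family: lognormal}
  # excess-homelessness mortality applied to *housed* states (0 in the base
  # case; a sensitivity scenario copies the unhoused values here)
  excess_homeless_out_housed: {base: 0.0, family: fixed}
  excess_homeless_in_housed:  {base: 0.0, family: fixed}
  induction_mortality_multiplier:
    methadone:     {base: 14.0, low: 1.07, high: 62.45, family: lognormal}
    buprenorphine: {base: 1.0, family: fixed}

overdose:
  # annual overdose incidence rates per person
  rate_out_housed:   {base: 0.1331, low: 0.0652, high: 0.2605, family: lognormal}
  rate_in_housed:    {base: 0.0567, low: 0.0283, high: 0.1098, family: lognormal}
  rate_out_unhoused: {base: 0.1368, low: 0.0665, high: 0.2700, family: lognormal}
  rate_in_unhoused:  {base: 0.0583, low: 0.0288, high: 0.1137, family: lognormal}
  # probability of surviving a single overdose event
  survival_housed:   {base: 0.880, low: 0.794, high: 0.943, family: beta}
  survival_unhoused: {base: 0.883, low: 0.798, high: 0.945, family: beta}
  # witnessing decomposition: survival = 1 - [w*d_w + (1-w)*d_u], with the
  # unwitnessed per-event death risk d_u a fixed multiple of the witnessed
  # risk d_w; used only by the witnessed-overdose sensitivity scenario
  witness_probability_housed:   {base: 0.6, family: fixed}
  witness_probability_unhoused: {base: 0.6, family: fixed}
  witness_probability_reference: 0.6
  witness_death_risk_ratio: 3.0

transitions:
  # annual rates per person; "housed"/"unhoused" follow the hazard-ratio
  # adjustment of the housed rates (printed values are authoritative)
  entry_housed:    {base: 0.426, low: 0.367, high: 0.489, family: lognormal}
  entry_unhoused:  {base: 0.213, low: 0.184, high: 0.245, family: lognormal}
  discontinuation:
    methadone:
      housed:   {base: 1.051, low: 0.578, high: 1.740, family: lognormal}
      unhoused: {base: 1.431, low: 0.783, high: 2.378, family: lognormal}
    buprenorphine:
      housed:   {base: 1.608, low: 1.004, high: 2.420, family: lognormal}
      unhoused: {base: 2.189, low: 1.361, high: 3.290, family: lognormal}
  success_housed:    {base: 0.316, low: 0.296, high: 0.337, family: lognormal}
  success_unhoused:  {base: 0.029, low: 0.028, high: 0.031, family: lognormal}
  abstinence_untreated_housed:   {base: 0.0791, low: 0.0040, high: 0.1549, family: lognormal}
  abstinence_untreated_unhoused: {base: 0.0074, low: 0.0040, high: 0.0144, family: lognormal}
  relapse_early_housed:    {base: 0.344, low: 0.300, high: 0.390, family: lognormal}
  relapse_early_unhoused:  {base: 0.462, low: 0.404, high: 0.524, family: lognormal}
  relapse_late_housed:     {base: 0.023, low: 0.0047, high: 0.0419, family: lognormal}
  relapse_late_unhoused:   {base: 0.031, low: 0.0063, high: 0.0564, family: lognormal}

hazard_ratios:
  # unhoused vs housed multiplicative adjustments (scenario/consistency use)
  entry: 0.50
  discontinuation: 1.36
  success: 0.09
  relapse: 1.35

housing:
  loss_rate: {base: 0.0820, low: 0.0739, high: 0.0903, family: lognormal}
  # state-group multipliers on the loss rate (a sensitivity scenario raises
  # them differentially for out-of-treatment / in-treatment individuals)
  loss_multiplier_out: 1.0
  loss_multiplier_in: 1.0
  loss_multiplier_abstinent: 1.0
  annual_cost: {base: 20900.0, family: fixed}

costs:
  # 2024 USD
  background_male_age30: 2764.0
  background_growth_rate: 0.034     # per year of age, repo default
  background_female_multiplier: 1.0 # repo default
  excess_oud_out:  {base: 8827.0,  low: 7966.0,  high: 9731.0,  family: lognormal}
  excess_oud_in:   {base: 7052.0,  low: 3675.0,  high: 10658.0, family: lognormal}
  excess_homeless: {base: 13823.0, low: 12475.0, high: 15257.0, family: lognormal}
  treatment:
    methadone:     {base: 8584.0, low: 7747.0, high: 9464.0, family: lognormal}
    buprenorphine: {base: 7836.0, low: 7077.0, high: 8629.0, family: lognormal}
  naloxone_per_provision: {base: 87.0, low: 79.0, high: 96.0, family: lognormal}
  per_overdose_housed:   {base: 3084.0, low: 1321.0, high: 6152.0, family: lognormal}
  per_overdose_unhoused: {base: 3029.0, low: 1297.0, high: 6043.0, family: lognormal}

qol:
  # quality-of-life multipliers per health state; out-of-treatment applies to
  # both the first-month and >1-month compartments
  out_housed:   {base: 0.668, low: 0.655, high: 0.680, family: beta}
  out_unhoused: {base: 0.290, low: 0.284, high: 0.295, family: beta}
  treatment_housed:   {base: 0.721, low: 0.700, high: 0.742, family: beta}
  treatment_unhoused: {base: 0.313, low: 0.304, high: 0.322, family: beta}
  abstinent_first_year_housed:   {base: 0.747, low: 0.728, high: 0.766, family: beta}
  abstinent_first_year_unhoused: {base: 0.324, low: 0.316, high: 0.333, family: beta}
  abstinent_ten_year_housed:   {base: 0.983, low: 0.970, high: 0.997, family: beta}
  abstinent_ten_year_unhoused: {base: 0.427, low: 0.421, high: 0.433, family: beta}
  # utility multiplier applied to housed values to represent being unhoused
  # (used by the higher-unhoused-quality-of-life scenario)
  homeless_utility_multiplier: 0.43

discount_rate: 0.03
# 1-month compartments (first month out of treatment; treatment induction)
# mature at 12 per year
first_month_exit_rate: 12.0
induction_exit_rate: 12.0

life_table:
  fixture: us_life_table_synthetic.csv
  # Gompertz-Makeham fallback (rate = c + A*exp(B*age)) fitted to the fixture
  gompertz_makeham:
    male:   {c: 1.12720e-03, A: 8.31597e-05, B: 0.0831753}
    female: {c: 4.85851e-04, A: 3.23195e-05, B: 0.0899448}
  max_age: 100
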