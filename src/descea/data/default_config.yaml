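# Canonical configuration: the published parameter table for the
# beta-lactam desensitization (DES) vs no-desensitization (NDES)
# cost-effectiveness model.  Costs in 2025 EUR; rates are proportions.
parameters:
  cost_per_patient:
    des_mean: 53665
    ndes_mean: 14102
    difference: 39563
    min: 11102
    max: 145441
    sd: 34270
    distribution: gamma
    alpha: 1.3        # shape (dimensionless)
    beta: 29685       # scale (EUR)
  cure_rate:
    des_mean: 0.714
    ndes_mean: 0.548
    difference: 0.166
    min: 0.133
    max: 0.199
    sd: 0.017
    distribution: beta
    alpha: 79.9
    beta: 401.6
  survival_rate:
    des_mean: 0.857
    ndes_mean: 0.714
    difference: 0.143
    min: 0.114
    max: 0.172
    sd: 0.015
    distribution: beta
    alpha: 82.2
    beta: 492.4

life_expectancy:
  mean_age: 73.3        # cohort mean age, years
  male: 80.3            # Spanish life expectancy, men
  female: 85.8          # Spanish life expectancy, women
  female_weight: 0.5    # unweighted sex average -> 9.75 remaining years

simulation:
  n_sims: 1000
  seed: 20250625
  wtp_thresholds: [25000, 30000]   # EUR per life-year gained

output:
  directory: results
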