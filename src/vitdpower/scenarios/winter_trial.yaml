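name: winter_trial
seed: 1
scheme: fixed
population:
  sigma_H: 5.0
  mu_A: 15.0
  sigma_A: 5.0
  floor: 10.0
fixed_dose:
  mu_omega: 0.8
  sigma_omega: 0.1
  gamma: 50.0
intensity:
  - {start: "09-01", end: "04-30", rate_per_week: 1.0}
  - {start: "05-01", end: "08-31", rate_per_week: 0.1}
risk:
  l: 1.0
infection:
  p0: 0.03
  refractory_mean_weeks: 2.0
trial:
  start: "11-01"
  duration_years: 0.5
  ratio: 1.0
grid:
  n: [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1100, 1200, 1300, 1400, 1500]
  mu: [15.0, 35.0, 50.0, 60.0, 75.0]
  dose: [10.0, 20.0, 40.0]
  u: [2.0]
mc:
  n_sims: 500
  replicates: 5
  n_boot: 500
  alpha: 0.05
  test: proportions
  n_jobs: 1
output:
  dir: results/winter_trial
  plots: true
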