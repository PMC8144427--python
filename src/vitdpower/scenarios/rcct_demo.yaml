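name: rcct_demo
seed: 1
scheme: concentration
population:
  sigma_H: 5.0
  mu_A: 15.0
  sigma_A: 5.0
  floor: 10.0
concentration:
  sigma_rho: 5.0
intensity:
  - {start: "09-01", end: "04-30", rate_per_week: 1.0}
  - {start: "05-01", end: "08-31", rate_per_week: 0.1}
risk:
  l: 1.0
infection:
  p0: 0.03
  refractory_mean_weeks: 2.0
trial:
  start: "09-01"
  duration_years: 1.0
  ratio: 1.0
grid:
  n: [100, 200, 400, 800]
  mu: [35.0, 50.0]
  dose: [50.0, 70.0]   # target threshold mean mu_rho (nmol/L) for the RCCT
  u: [2.0]
mc:
  n_sims: 200
  replicates: 3
  n_boot: 500
  alpha: 0.05
  test: means
  n_jobs: 1
output:
  dir: results/rcct_demo
  plots: false
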