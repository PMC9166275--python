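# Default analysis configuration: packaged 2014-2021 survey series,
# published harvest rates, published priors, six projection bands.
# surveys/harvest paths omitted -> packaged data is used.
timing: escapement
priors:
  k_bounds: [900000, 2000000]
  r_max_bounds: [0.500, 2.000]
  sigma_bounds: [0.01, 1.0]
mcmc:
  n_chains: 4
  n_iter: 50000
  n_burn: 25000
  seed: 0
scenarios:
  - {label: "0.001-0.100", lower: 0.001, upper: 0.100, horizon: 9}
  - {label: "0.101-0.300", lower: 0.101, upper: 0.300, horizon: 9}
  - {label: "0.301-0.500", lower: 0.301, upper: 0.500, horizon: 9}
  - {label: "0.501-0.700", lower: 0.501, upper: 0.700, horizon: 9}
  - {label: "0.701-0.900", lower: 0.701, upper: 0.900, horizon: 9}
  - {label: "0.001-0.900", lower: 0.001, upper: 0.900, horizon: 9}
report:
  n_projection_draws: 20000
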