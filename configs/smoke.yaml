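# Small end-to-end configuration: every pipeline stage runs in seconds.
outdir: results/smoke
seed: 1
simulate:
  n_lakes: 6
  n_species: 2
  years_per_lake: 2
  fish_per_survey: 100
growth_mcmc:
  chains: 2
  iterations: 500
  burn_in: 200
  thin: 2
longevity_mcmc:
  chains: 2
  iterations: 800
  burn_in: 300
  thin: 2
regimes: [5, 50, 95]
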