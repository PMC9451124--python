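# Demo: 100-area synthetic survey, full pipeline
outdir: demo_out
seed: 7
simulate:
  n_areas: 100
  layout: grid
model:
  covariates: [edu_low_share, male_share]
  n_chains: 2
  n_iter: 2000
  burn_in: 800
sam:
  n_draws: 1000
  rr_study: shavelle
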