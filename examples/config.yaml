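n_visits: 5000
seed: 3
mu_true: 0.0
no_prior_fraction: 0.5
covariate_missing_rate: 0.1
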