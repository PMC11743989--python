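# Example run configuration for `cogfoot run --config analysis/run_config_example.yaml`
# (equivalent to the analysis/0*.py drivers, but config-driven).
seed: 1
outdir: results/cli_run
input:
  mode: synthetic
  scenario:
    n_participants: 5000
    seed: 1
    age_range: [40, 70]
    sex_ratio: 0.542
    covariates:
      - {name: bmi, mean: 27.0, sd: 4.5, effects: {FI: -0.01, PM: -0.01}}
    medications:
      - {code: N02BE01, prevalence: 0.199, effects: {FI: -0.05, RT: 0.05, PM: -0.10}}
      - {code: M01AE01, prevalence: 0.126, effects: {FI: 0.03, RT: -0.03, PM: 0.06}}
      - {code: M01AX05, prevalence: 0.045, effects: {FI: 0.06, RT: -0.06, PM: 0.10}}
      - {code: B01AC06, prevalence: 0.122}
      - {code: C10AA01, prevalence: 0.124}
    outcomes:
      - {name: FI, loading: 0.8, age_effect: -0.02, missing_fraction: 0.05}
      - {name: RT, larger_is_better: false, loading: 0.5, age_effect: 0.025}
      - {name: PM, kind: binary, intercept: 1.186, loading: 0.6, age_effect: -0.02}
pca_cognition:
  enabled: true          # composite over the continuous tests
atc_levels: [4, 5]
horseshoe:
  n_iter: 2000
  burn_in: 500
population:
  total: 24600000        # illustrative synthetic population aged 40-70
top_k: 10
log_level: INFO
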