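# Versioned registry of every protocol constant used by the analysis.
# Values here mirror the defaults hard-wired in the package; deviations in a
# study configuration are therefore diffable against this file.
priors:
  vfd:
    neutral: {mu: 0.0, sigma: 0.35}
    optimistic: {mu: 0.7, sigma: 1.34}
    pessimistic: {mu: -0.7, sigma: 1.34}
    survey: {mu: 0.13, sigma: 0.35, printed_alternative: {mu: 0.0, sigma: 0.6}}
  mortality_28d:
    neutral: {mu: 0.0, sigma: 0.35}
    optimistic: {mu: -0.16, sigma: 0.3}
    pessimistic: {mu: 0.7, sigma: 1.34}
    survey: {mu: 0.0, sigma: 0.075}
  duration:
    neutral: {mu: 0.0, sigma: 1.02}
    optimistic: {mu: -0.4, sigma: 0.76}
    pessimistic: {mu: 0.4, sigma: 0.76}
    survey: {mu: 0.0, sigma: 0.76}
heterogeneity:
  half_normal_scale: 0.5
elicited_survey:
  vfd_smd: 0.07
  vfd_smd_95ci: [-0.31, 0.45]
  mortality_control_risk: 0.29
  mortality_risk_difference: 0.0
  mortality_rd_95ci: [-0.03, 0.03]
  duration_md_days: 0.0
  duration_md_95ci: [-1.0, 2.0]
thresholds:
  rope_or: [0.9, 1.1]
  rope_log_or_literal: [-0.1, 0.1]
  superiority_posterior_probability: 0.975
  secondary_report_probability: 0.95
  severe_harm_or_vfd: 0.75
  severe_harm_or_mortality: 1.25
subgroup_cutoffs:
  bmi: "> 30"
  pf_ratio: "<= 200"
  lips: ">= 4"
  apache: ">= 86"
  cardiac_arrest: "yes vs no"
  surgical_admission: "surgical vs non-surgical"
  primary_respiratory_failure: "primary respiratory failure vs other"
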