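# Synthetic per-strategy screening-attendance models (logit link).
#
# The published study fitted four beta-regression participation models (one
# per screened disease combination) to survey data; the coefficient vectors
# are unpublished.  These stand-ins preserve the mechanism -- independent
# per-strategy logistic predictors over age, sex, smoking status, family
# history of lung cancer, prior COPD/CVD diagnosis, pack-years and the two
# published interactions -- and reproduce the published summary statistics
# (population mean participation ~0.75 inside the attainable range
# 0.63-0.974).  Predictors are centred/scaled inside the code: z_age =
# (age-61)/5.7, z_py = (pack_years-48)/20.
#
# p = clip(expit(intercept + ...), floor, ceiling) with floor/ceiling the
# published attainable range.
LC:
  intercept: 1.0986   # logit(0.75)
  z_age: -0.10
  male: 0.05
  current_smoker: -0.15
  family_history_lc: 0.25
  prior_dx: 0.10
  z_pack_years: 0.05
  current_x_prior_dx: -0.05
  z_age_x_z_pack_years: -0.04
LC+COPD:
  intercept: 1.0886
  z_age: -0.11
  male: 0.04
  current_smoker: -0.18
  family_history_lc: 0.22
  prior_dx: 0.16
  z_pack_years: 0.06
  current_x_prior_dx: -0.08
  z_age_x_z_pack_years: -0.04
LC+CVD:
  intercept: 1.0936
  z_age: -0.09
  male: 0.06
  current_smoker: -0.16
  family_history_lc: 0.22
  prior_dx: 0.14
  z_pack_years: 0.05
  current_x_prior_dx: -0.06
  z_age_x_z_pack_years: -0.03
Big-3:
  intercept: 1.0786
  z_age: -0.12
  male: 0.05
  current_smoker: -0.20
  family_history_lc: 0.20
  prior_dx: 0.18
  z_pack_years: 0.06
  current_x_prior_dx: -0.10
  z_age_x_z_pack_years: -0.05
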