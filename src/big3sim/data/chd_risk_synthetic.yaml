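# Synthetic stand-in coefficient set for the annual CHD event-risk equation.
#
# Structure mirrors CAC-informed CHD risk scores: a logistic linear predictor
# over age, sex, smoking status, pack-years and coronary-artery-calcium (CAC)
# category.  The numeric values are NOT transcribed from any publication; they
# were constructed so that a synthetic NLST-like cohort (heavy smokers aged
# 55-74) has a mean annual CHD event risk of roughly 1.2%/y, rising with age
# and CAC burden.  Replace this file with transcribed coefficients to use a
# published equation.
#
# annual risk = expit(intercept + age_per_year*(age-61) + male*I(male)
#                     + current_smoker*I(current) + pack_years_per10*(py-48)/10
#                     + cac[category])
intercept: -5.95
age_per_year: 0.055
male: 0.35
current_smoker: 0.45
pack_years_per10: 0.04
cac:
  none: 0.0
  mild: 0.55
  moderate: 1.1
  severe: 1.75
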