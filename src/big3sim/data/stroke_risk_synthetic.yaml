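# Synthetic stand-in coefficient set for the annual stroke-risk equation.
#
# Structure mirrors the Framingham stroke risk profile (age, sex, smoking),
# deliberately WITHOUT any coronary-calcium term: calcium scores must not
# enter the stroke linear predictor.  Values are constructed (not transcribed)
# to give a mean annual stroke risk of roughly 0.5%/y in a synthetic
# NLST-like cohort; replace with transcribed coefficients to use the
# published equation.
intercept: -5.70
age_per_year: 0.065
male: 0.15
current_smoker: 0.40
pack_years_per10: 0.02
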