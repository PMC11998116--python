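# big3sim

Individual-level microsimulation and cost-utility analysis of combined
low-dose-CT (LDCT) screening for the **Big-3** diseases — lung cancer (LC),
chronic obstructive pulmonary disease (COPD) and cardiovascular disease
(CVD) — in a high-risk population of heavy current and former smokers.

A single LDCT scan can detect all three diseases: pulmonary nodules (LC),
emphysema (COPD) and coronary-artery calcium (subclinical atherosclerotic
CVD).  The open question for screening policy is whether reading the scan
for COPD and/or CVD on top of LC screening buys enough extra health to
justify the extra cost.  `big3sim` answers that question in a decision-
analytic framework aimed at health-economic modellers: it simulates a
synthetic NLST-eligible cohort (ages 55–74, >30 pack-years, quit <15 years
ago) month by month over a lifetime under five strategies — no screening,
LC, LC+COPD, LC+CVD, Big-3 — and compares them in a fully incremental
cost-utility analysis.

## The model in brief

* **Lung cancer.** Tumours arise with an individual monthly hazard derived
  from a 6-year risk (calibrated so lifetime cumulative incidence is 0.22),
  start at 0.33 mm and grow exponentially in volume with an individually
  sampled volume doubling time (VDT): diameter d(t) = 0.33 · 2^(t / 3·VDT).
  LDCT sensitivity is piecewise-linear in diameter (0 below 3 mm,
  0.5·d − 1.5 on [3, 5) mm, 1 at ≥5 mm); specificity is 0.992.  Without
  screening, a tumour surfaces at its self-detection diameter
  (gamma(3.74, 0.08) truncated at 40 mm).  Stage at detection follows a
  calibrated ordered-logit model in log-diameter — the mechanism behind the
  screening **stage shift** — and survival after diagnosis is stage-specific
  Gompertz, h(t) = b·e^{c·t}.
* **COPD.** Per-sex Fleischner emphysema severity, Poisson exacerbations
  (annual rates 0.754–1.35 by severity), treatment (RR 0.82) and cessation
  (RR 0.78) effects, and COPD mortality via prior-year exacerbation hazard
  ratios (2.00 / 4.13) on a calibrated base hazard.
* **CVD.** Individual annual CHD and stroke risks (risk-equation based, with
  coronary calcium entering CHD risk only); recurrent events with the
  published type mix (MI 45%, angina 35%, CHD death 16%, arrest 4%);
  statins (RR 0.62 CHD / 0.83 stroke) and ACE inhibitors (0.79 / 0.86)
  assigned after a moderate/severe calcium finding at the baseline round.
* **Economics.** 2022-€ costs and utility weights per cycle, discounted at
  4%/y (costs) and 1.5%/y (effects); incremental cost-utility ratios
  (ICUR = ΔC/ΔE), strong and extended dominance, the efficiency frontier,
  probabilistic sensitivity analysis (PSA) with full re-simulation per draw,
  and cost-effectiveness acceptability curves (CEAC) over willingness-to-pay.

See `docs/methods.md` for assumptions, calibration details and limitations.

## Worked example

```python
import big3sim as b3

params = b3.default_parameters()                       # shipped, calibrated
cohort = b3.generate_cohort(b3.CohortConfig(n_individuals=10_000, seed=1), params)
results = b3.run_strategies(cohort, b3.default_strategies(), params, seed=1)
frontier = b3.incremental_analysis(b3.outcomes_from_results(results))
print(b3.cea_table(frontier).to_string(index=False))
```

prints (costs €/person, effects QALYs/person, discounted, lifetime horizon):

```
    Strategy   Total Cost  Total Effect  Incremental Cost  Incremental Effect ICUR/classification
No screening 10648.608544     15.397826               NaN                 NaN
          LC 12250.989199     15.562848               NaN                 NaN    Weakly dominated
      LC+CVD 12448.405809     15.639411       1799.797266            0.241585                7450
     LC+COPD 12910.700051     15.566375               NaN                 NaN           Dominated
       Big-3 13115.417881     15.644315        667.012071            0.004904              136000
```

Reading it: LC-only screening is *weakly (extendedly) dominated* — adding
CVD reading to the scan buys more QALYs per euro than LC alone, so the
efficiency frontier jumps from no screening straight to LC+CVD at
≈€7,450 per QALY (≈€1,800 extra cost and ≈0.24 extra QALYs per person).
LC+COPD is *strongly dominated*: LC+CVD is both cheaper and more effective.
Extending to Big-3 costs ≈€136,000 per extra QALY — far above the Dutch
willingness-to-pay thresholds (€20,000–80,000/QALY) — because COPD reading
adds little health on top.  The same cohort shows the stage shift the
screening benefit rests on: 35.8% of diagnoses within 10 years are stage I
without screening versus 72.1% with annual LC screening (this run).

The `big3sim` command-line tool wraps the same pipeline
(`generate-cohort`, `simulate`, `calibrate`, `psa`, `analyze`); try
`big3sim simulate --cohort cohort.csv --strategy LC+CVD --seed 1 --out out/`.

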