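# Methods

`big3sim` is an individual-level state-transition microsimulation of combined
low-dose-CT (LDCT) screening for the "Big-3" diseases — lung cancer (LC),
COPD and cardiovascular disease (CVD) — in a high-risk population of heavy
(ex-)smokers, coupled to a fully incremental cost-utility analysis.  This
note describes the model, its assumptions, the calibration procedure, the
synthetic cohort, and the numerical and design choices a user should know
before trusting (or editing) the defaults.

## Model structure

Individuals are simulated one month at a time from cohort entry (ages 55–74)
until death, capped at age 100 (residual survivors contribute a terminal
cycle).  Within a cycle, events run in a fixed order: (1) other-cause death,
(2) lung-tumour onset and growth, (3) a screening round when due,
(4) symptomatic tumour detection, (5) COPD exacerbation draws, (6) CHD and
stroke event draws, (7) disease-specific deaths, (8) cost and QALY accrual.
Detection therefore precedes same-cycle disease mortality.  When several
death causes fire in one cycle, a documented precedence (other-cause, LC,
COPD, CVD) decides the recorded cause; this matters only in the rare
multi-fire cycles.  No half-cycle correction is applied — with monthly
cycles the bias is negligible relative to Monte-Carlo noise.

All stochastic inputs are pre-drawn per individual from streams derived only
from the run seed: exponential "hazard budget" latents for onset and each
death cause (an event fires when accumulated hazard crosses the latent),
cumulative-exponential thresholds for recurrent CHD/stroke events, and
uniform quantiles for counts and categorical choices.  Two consequences:
runs are bit-reproducible, and strategies compared under the same seed share
identical latent disease histories (common random numbers), so incremental
costs and effects are far less noisy than independent runs would give.
Quantile coupling extends to counts: exacerbation counts under treatment use
the same uniform as untreated counts with a smaller Poisson mean.

## Lung cancer natural history

A tumour appears at 0.33 mm and grows exponentially in volume with an
individually sampled volume doubling time (VDT, lognormal with log-mean 4.59
and log-SD 0.2198 days — geometric mean ≈ 98.5 days); a spherical tumour's
diameter therefore doubles every 3 VDTs.  Each tumour carries a
self-detection diameter drawn from a gamma distribution (shape 3.74, rate
0.08/mm) truncated at 40 mm, at which symptoms trigger diagnosis without
screening.  (The source quotes a 45.9 mm mean alongside these shape/rate
values and the 40 mm cap; shape/rate plus truncation is the consistent
reading and is what we implement.)

Onset risk is individual: a 6-year LC risk drawn per smoking status (beta
matched to mean 0.10068 current / 0.06526 former, SD 0.05, truncated to
0.006–0.323), converted to a monthly hazard.  A flat lifetime extrapolation
of a 6-year risk overshoots the published lifetime cumulative incidence in
heavy smokers (0.22): the engine therefore rescales the onset hazard by a
calibrated factor (default 0.57) so simulated lifetime incidence matches
0.22.  Quitting smoking rescales an individual's risk by the ratio of the
status-level means.  At most one tumour per individual is simulated (plus a
fresh draw for individuals whose warm-up tumour is removed, see below);
second primaries are out of scope.

Stage at detection follows a diameter-indexed ordered-logit model over stage
groups I–IV: P(group ≤ k | d) = expit(c_k − β ln d).  Larger tumours are
stochastically later-stage by construction.  Substages split I into IA/IB at
30 mm and II/III by fixed fractions (0.5/0.6).  β and the cutpoints are
calibration targets (below).  After diagnosis, LC mortality follows
stage-specific Gompertz hazards h(t) = b·e^{c·t} in months since diagnosis,
with the published (c, b) pairs per substage; negative c yields cure
fractions (e.g., ≈75% for IA, ≈15% for IV, stage-IV median survival ≈ 6
months).  Stages IA–IIIA are operable: a once-off surgery cost applies at
diagnosis; monthly stage costs run for the stage-specific treatment
duration (20.9 months I–III, 12.6 months IV).

### Warm-up

Screening round 1 must see prevalent, undetected tumours.  Before the main
simulation, onset runs for a warm-up period (default 120 months; only
tumour dynamics, no aging, deaths or accrual); tumours that have reached
their self-detection diameter by the end of warm-up are removed (those
cancers would have surfaced before the programme started) and the individual
reverts to tumour-free with a fresh onset latent.  The remaining prevalent
tumours are undetected by construction.

## Screening pathway

Annual LDCT between ages 55 and 74 for whichever of {LC, COPD, CVD} the
strategy names; LC is always screened (COPD/CVD are additional readings of
the same scan).  Everyone eligible is invited (invitation cost €6 regardless
of attendance); attendance is a per-round Bernoulli draw at a per-individual
probability from a strategy-specific logistic model over age, sex, smoking
status, family history of LC, prior COPD/CVD diagnosis, pack-years, and the
two published interactions, clipped to the published attainable range
0.63–0.974 with population mean ≈ 0.75.  The four coefficient vectors are
unpublished; the shipped file is a synthetic, structure-preserving stand-in
(see `data/attendance_synthetic.yaml`) and is fully replaceable.  The four
models are independent: an individual may attend LC screening but decline
Big-3.

The LC reading has diameter-dependent sensitivity (0 below 3 mm, 0.5·d − 1.5
between 3 and 5 mm, 1 at ≥5 mm; the published "d ≤ 5 mm = 100%" clause is
read as d ≥ 5 mm, the only reading consistent with the other two clauses)
and specificity 0.992.  A positive screen triggers diagnostic work-up
(€1747); false positives return to the eligible pool next cycle with no
disutility (the source is silent).  Emphysema and coronary-calcium findings
are evaluated at each individual's first attended round only: moderate or
worse emphysema leads to COPD diagnosis and exacerbation-limiting treatment
(rate ×0.82); moderate/severe coronary calcium leads to preventative
treatment — statins with a configurable proportion (default 0.35) and ACE
inhibitors for 22% of those without CVD history.  Assignments persist for
life.  Individuals with diagnosed LC, or older than 74, are never screened
again.

Smoking cessation is screening-linked but result-independent: each current
smoker has one latent quit draw; with probability `p_base` (default 0.11)
they quit at simulation start, and screening participants get one upgrade
chance to `p_screen ≥ p_base` (default 0.21) at their first attended round.
The defaults reproduce the published quitter counts (≈542 and ≈898 per
10,000); the PSA samples the published uniform ranges (0–0.6 and 0.1–0.6
with the ordering constraint).  Quitting lowers LC onset risk, exacerbation
rates (×0.78) and switches CHD/stroke risks to their former-smoker values.

## COPD and CVD

Every individual carries a Fleischner emphysema severity drawn from the
published per-sex tables (men: 34/41/22/1/2%, women: 40/51/7/1/1%).
Exacerbations are Poisson with severity-specific annual rates
(0.754/0.865/1.095/1.35), split moderate/severe with a severe share of
0.079 (derived from the published lifetime counts).  Outside screening,
each exacerbation leads to COPD diagnosis (and treatment) with probability
0.0135 — anchored to the published lifetime diagnosis counts; the published
year-1 count implies a ~25× larger value and is irreconcilable with the
lifetime one, so lifetime behaviour (which drives the economics) wins.
COPD death applies a calibrated base monthly hazard (default 1.04e-4)
multiplied by the prior-12-month exacerbation hazard ratio (1 / 2.00 / 4.13
for 0 / 1–2 / 3+).  GOLD-grade disutility attaches to the underlying
emphysema severity (diagnosed or not); COPD maintenance costs begin at
diagnosis.

Annual CHD and stroke risks are assigned at entry from logistic risk
equations over age, sex, smoking, pack-years and (CHD only — never stroke)
coronary-calcium category.  The true published coefficient sets are not
reproducible here; the shipped files are synthetic stand-ins with the right
structure and realistic population means (~1.2%/y CHD, ~0.5%/y stroke),
chosen together with the CAC category distribution so that 10-year CVD
deaths and treatment counts are of the order of the published intermediate
outcomes.  Risks are fixed at their entry-age values for life (a documented
simplification).  Events recur (thresholded cumulative hazards); CHD event
types follow the published split (MI 45%, angina 35%, CHD death 16%,
cardiac arrest 4%).  CHD-death events are fatal; cardiac-arrest fatality
defaults to 0 (unstated in the source); stroke case fatality defaults to
0.15 (our assumption — it makes total atherosclerotic-CVD deaths exceed
CHD-type deaths, as the published counts require).  Statins multiply CHD
risk by 0.62 and stroke by 0.83; ACE inhibitors by 0.79/0.86; both apply
multiplicatively when co-prescribed.

Other-cause mortality is an age-graded exponential hazard anchored at the
published aggregate 0.01/y at a reference age of 72 and doubling every ~8
years (the general-population gradient); a log-slope of 0 recovers a flat
0.01/y.  The age grading is what the source describes (age/sex-based) and is
needed to reproduce its 10-year death counts and total-effect scale; a flat
1%/y would leave most of the cohort alive at 100.

## Economics

Costs are 2022 euros, discounted at 4.0%/y; QALYs at 1.5%/y; per-cycle
factors (1+r)^(−month/12) anchored at simulation start.  A cycle's utility
is the age-band baseline (0.857 / 0.839 / 0.852 for ≤60 / 60–70 / >70)
multiplied by every applicable condition multiplier: COPD GOLD grade
(0.90/0.76/0.75/0.55, mapping Fleischner mild→GOLD 1 … very severe→GOLD 4),
LC stage group (0.71/0.68/0.67/0.66), an exacerbation this month
(0.98 moderate / 0.95 severe), and CVD event recency (stroke 0.64 in the
event month then 0.80; CHD 0.883 then 0.884).  Multiplicative combination
for comorbidity is a modelling choice (the source publishes only the
individual "relative disutilities"); it guarantees utility never exceeds
baseline.  Individuals dying in a cycle accrue that cycle's event costs but
no utility.  Stroke costs run €2936/month for months 1–6 and €780 for
months 7–13 after the event.

## Calibration

Four quantities are fitted, in this order, all deterministic given a seed
and using common random numbers:

1. **Onset hazard scale** — iterative proportional fitting (log-survival
   scale) so lifetime cumulative LC incidence ≈ 0.22.
2. **Stage model (β, c₁..c₃)** — the stage model affects only post-diagnosis
   survival, never which tumours are detected when, so one no-screening and
   one LC-screening run suffice to collect the empirical 10-year detection
   diameters; for any slope β the three cutpoints then solve the
   no-screening stage targets exactly (monotone 1-D root-finds over the
   empirical diameters), and β is fitted to the LC-screening targets by a
   bounded scalar search on expected (not sampled) stage distributions.
   Targets: stage I/II/III/IV = 37.5/8.8/19.1/34.7% without screening and
   70.3/6.3/11.3/12.2% with.  An analytic initialisation against the
   truncated-gamma self-detection law is also provided
   (`solve_stage_cutpoints`).
3. **COPD base hazard** — proportional fitting to 130 COPD deaths per
   10,000 in 10 years (no-screening arm).
4. Warm-up length and the self-detection mean can be freed as outer
   Nelder-Mead parameters (the round-1 detection-rate target is a
   configurable input, not printed in the source); the defaults leave them
   at 120 months and shape/rate.

The shipped defaults are the fitted values at a development seed; the
acceptance script and test suite re-run the full calibration from scratch
at their own seeds.

## Probabilistic sensitivity analysis

Each PSA draw samples a complete parameter set — beta for probabilities,
utilities and relative risks (moment-matched), gamma for costs, truncated
normal for treatment durations and for the COPD hazard ratios inside their
95% CIs (HR(3+) forced ≥ HR(1–2)), Dirichlet for CHD event types, and the
published uniforms for cessation with p_screen ≥ p_base — then regenerates
the cohort and re-simulates every strategy with common random numbers for
that draw; no emulator or shortcut.  Dispersions quoted as mean±SD are
capped at a 20% coefficient of variation for PSA purposes: several quoted
SDs are patient-level dispersions (cost per exacerbation 525 ± 8049;
treatment duration 20.9 ± 26 months; mean utilities ± 0.18–0.31) which,
used verbatim as mean-parameter uncertainty, produce degenerate draws
(a gamma with shape 0.004 is ≈0 almost surely).  The 20% ceiling is the
source's own fallback convention for costs without dispersion data;
interval-based inputs (HR CIs, attendance range, cessation uniforms) are
sampled from their printed intervals unchanged.

The CEAC reports, per willingness-to-pay λ on a 0–150,000 € grid, the
fraction of draws in which each strategy maximises net monetary benefit
λ·E − C, ties split equally.  Run count and per-draw cohort size are
configurable; the packaged analyses use 100 draws × 2,000 individuals,
which keeps a 5-strategy PSA around five minutes on one CPU while leaving
the strategy ranking stable at the Dutch thresholds (20/50/80 k€/QALY).

## Synthetic cohort

The original study samples individuals from restricted NLST data.  The
generator emulates that population from configurable marginals: ages 55–74
(5-year bands weighted 43/31/18/8%), 59% male, 48.67% current smokers,
pack-years 30 + gamma (mean ≈ 56, median ≈ 48) with an optional Gaussian
copula correlation to age (default 0.2), former smokers quit uniformly
0–15 years ago, 22% family history of LC, 15% prior CVD, 5% prior COPD
diagnosis, and a CAC category distribution (25/25/30/20%) chosen so
referral and treatment counts are of the order of the published ones.  What
it does **not** reproduce: the true NLST joint distribution (only marginals
plus one copula), ethnicity, within-person risk-factor trajectories, or
age-stratified emphysema severity (the published sex aggregates are used;
an override hook exists).  Passing tests therefore show the method behaves
correctly under NLST-like marginal conditions, not that results transfer
to any particular real cohort.

## Numerical choices

Monthly Poisson counts are drawn by an inverse-CDF loop truncated at k = 9
(mass beyond is < 1e-12 at the largest monthly rate 1.35/12), preserving
quantile coupling across strategies; scipy's distributions back it in
tests.  Recurrent CVD events are capped at 10 CHD and 6 stroke events per
individual (expected lifetime counts are ≲1).  Growth, conversion and
discounting use closed forms; the growth law is validated against monthly
compounding to 1e-9 relative error.  Degenerate inputs (zero hazards, zero
budgets, empty strategies, single-strategy frontiers, exact outcome ties)
are handled explicitly and tested.

## Known limitations

- Diameter is the sole tumour descriptor (spherical tumours; no histology
  split, no nodule-management protocol, no radiation-induced cancers).
- CHD/stroke risks and the attendance model use synthetic stand-in
  coefficients; absolute CVD and participation levels inherit that.
- CVD risk does not age after entry; emphysema severity does not progress.
- No interaction between emphysema and CVD mortality.
- One tumour per individual (plus the warm-up replacement draw).
- COPD diagnosis outside screening uses a single per-exacerbation
  probability; the source's year-1 and lifetime diagnosis counts cannot
  both be matched by any such rule (the lifetime count is matched).
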