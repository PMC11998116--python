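"""Monthly-cycle microsimulation engine.

Simulates every individual of a cohort until death (lifetime horizon, capped
at age 100) under one screening strategy, accruing discounted costs and QALYs
and the intermediate outcome counts (deaths by cause at 10 years,
exacerbations, diagnoses, CVD events, treatment uptake, stage distribution).

Event order within a cycle: (1) other-cause death, (2) tumour onset/growth,
(3) screening round if due, (4) symptomatic detection, (5) exacerbation
draws, (6) CVD event draws, (7) disease-specific deaths resolved under the
documented precedence (other-cause, LC, COPD, CVD), (8) cost/QALY accrual.
No half-cycle correction is applied (monthly cycles make it negligible).
Individuals dying in a cycle accrue that cycle's event costs but no utility.

Common random numbers: all stochastic inputs are pre-drawn per individual
from streams derived only from the seed — exponential "hazard budget"
latents for onset and each death cause, event-time thresholds for recurrent
CVD events, and uniform quantiles for counts and choices.  Running two
strategies with the same seed therefore reuses identical latent disease
histories; only screening-dependent downstream events differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (ParameterSet, DAYS_PER_MONTH, SUBSTAGES, STAGE_GROUPS,
                     SUBSTAGE_TO_GROUP, EMPHYSEMA_LEVELS, CAC_LEVELS)
from .screening import StrategySpec, attendance_probability
from .population import load_attendance_coeffs

_N_STREAMS = 16
_K_CHD = 10   # max recurrent CHD events per individual
_K_STR = 6
_POISSON_KMAX = 9

CAUSES = ("other", "lc", "copd", "cvd")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Per-strategy totals and intermediate-outcome counts."""

    strategy: str
    n_individuals: int
    seed: int
    mean_cost: float
    mean_qaly: float
    counts: dict = field(default_factory=dict)
    stage_distribution_10y: dict = field(default_factory=dict)
    detected_diameters_10y: np.ndarray | None = None
    per_individual: pd.DataFrame | None = None
    ledger: dict | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_individuals": self.n_individuals,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "counts": {k: float(v) for k, v in self.counts.items()},
            "stage_distribution_10y": dict(self.stage_distribution_10y),
        }


# ---------------------------------------------------------------------------
# latent randomness
# ---------------------------------------------------------------------------


@dataclass
class Latents:
    """Strategy-independent random inputs for one (cohort, seed) pair."""

    E_onset1: np.ndarray
    E_onset2: np.ndarray
    vdt1: np.ndarray
    vdt2: np.ndarray
    thr1: np.ndarray
    thr2: np.ndarray
    u_stage1: np.ndarray
    u_stage2: np.ndarray
    u_quit: np.ndarray
    E_oc: np.ndarray
    E_lc: np.ndarray
    E_copd: np.ndarray
    chd_thresholds: np.ndarray     # (n, K) cumulative Exp(1)
    u_chd_type: np.ndarray
    u_chd_fatal: np.ndarray
    stroke_thresholds: np.ndarray
    u_stroke_fatal: np.ndarray
    u_att: np.ndarray              # (n, R)
    u_test: np.ndarray
    u_statin: np.ndarray
    u_ace: np.ndarray
    u_statin_bg: np.ndarray
    u_ace_bg: np.ndarray
    U_exac: np.ndarray             # (n, T) float32
    U_sev: np.ndarray
    U_copddx: np.ndarray


def draw_latents(n: int, T: int, n_rounds: int, params: ParameterSet,
                 seed: int) -> Latents:
    streams = [np.random.default_rng(c)
               for c in np.random.SeedSequence(seed).spawn(_N_STREAMS)]
    lc = params.lung_cancer
    from .natural_history import sample_self_detection_diameter

    def trunc_gamma(rng):
        return sample_self_detection_diameter(params, rng, size=n)

    return Latents(
        E_onset1=streams[0].exponential(size=n),
        E_onset2=streams[0].exponential(size=n),
        vdt1=streams[1].lognormal(lc.vdt_log_mean, lc.vdt_log_sd, size=n),
        vdt2=streams[1].lognormal(lc.vdt_log_mean, lc.vdt_log_sd, size=n),
        thr1=trunc_gamma(streams[2]),
        thr2=trunc_gamma(streams[2]),
        u_stage1=streams[3].random(n),
        u_stage2=streams[3].random(n),
        u_quit=streams[4].random(n),
        E_oc=streams[5].exponential(size=n),
        E_lc=streams[6].exponential(size=n),
        E_copd=streams[7].exponential(size=n),
        chd_thresholds=np.cumsum(streams[8].exponential(size=(n, _K_CHD)), axis=1),
        u_chd_type=streams[8].random((n, _K_CHD)),
        u_chd_fatal=streams[8].random((n, _K_CHD)),
        stroke_thresholds=np.cumsum(streams[9].exponential(size=(n, _K_STR)), axis=1),
        u_stroke_fatal=streams[9].random((n, _K_STR)),
        u_att=streams[10].random((n, n_rounds)),
        u_test=streams[11].random((n, n_rounds)),
        u_statin=streams[12].random(n),
        u_ace=streams[12].random(n),
        u_statin_bg=streams[12].random(n),
        u_ace_bg=streams[12].random(n),
        U_exac=streams[13].random((n, T), dtype=np.float32),
        U_sev=streams[14].random((n, T), dtype=np.float32),
        U_copddx=streams[15].random((n, T), dtype=np.float32),
    )


# ---------------------------------------------------------------------------
# small inverse-CDF helpers (vectorised, cheap per cycle)
# ---------------------------------------------------------------------------


def _poisson_icdf(u: np.ndarray, mu: np.ndarray, kmax: int = _POISSON_KMAX) -> np.ndarray:
    """Quantile of Poisson(mu) at u, truncated at kmax (negligible mass beyond)."""
    pmf = np.exp(-mu)
    cdf = pmf.copy()
    k = np.zeros(mu.shape, dtype=np.int16)
    for i in range(1, kmax + 1):
        k += u > cdf
        pmf = pmf * mu / i
        cdf += pmf
    return k


def _binom_split(u: np.ndarray, k: np.ndarray, p: float) -> np.ndarray:
    """Quantile of Binomial(k, p) at u; k small (severe-exacerbation split)."""
    out = np.zeros(k.shape, dtype=np.int16)
    nz = k > 0
    if nz.any():
        from scipy.stats import binom
        out[nz] = binom.ppf(u[nz], k[nz], p).astype(np.int16)
    return out


# ---------------------------------------------------------------------------
# warm-up
# ---------------------------------------------------------------------------


@dataclass
class WarmupState:
    """Latent tumour state at the first screening round."""

    present: np.ndarray        # prevalent undetected tumour
    onset_month: np.ndarray    # float months, <= 0 for prevalent tumours
    removed: np.ndarray        # warm-up tumour grew past its threshold -> dropped
    E_remaining: np.ndarray    # leftover onset hazard budget for tumour-free people
    use_slot2: np.ndarray      # removed individuals draw their next tumour from slot 2


def warmup(onset_hazard_monthly: np.ndarray, months: int,
           lat: Latents, params: ParameterSet) -> WarmupState:
    """Run the pre-screening warm-up and drop already-detectable tumours.

    Tumours onset under each individual's monthly hazard over ``months``
    cycles before screening starts and grow by the growth law; any tumour at
    or past its self-detection diameter at the end of warm-up is removed
    (the individual reverts to tumour-free and a fresh latent governs any
    later tumour).  Deterministic given the latents.
    """
    if months < 0:
        raise ValueError("warm-up months must be >= 0")
    lam = np.asarray(onset_hazard_monthly, dtype=float)
    consumed = lam * months
    onset_in_warmup = lat.E_onset1 < consumed
    # continuous onset time relative to screening start (negative)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(onset_in_warmup, lat.E_onset1 / np.maximum(lam, 1e-300) - months, 0.0)
    d0 = params.lung_cancer.start_diameter_mm
    growth_months = -tau
    d_at_start = d0 * np.exp2(growth_months * DAYS_PER_MONTH / (3.0 * lat.vdt1))
    removed = onset_in_warmup & (d_at_start >= lat.thr1)
    present = onset_in_warmup & ~removed
    E_remaining = np.where(onset_in_warmup, np.inf, lat.E_onset1 - consumed)
    E_remaining = np.where(removed, lat.E_onset2, E_remaining)
    return WarmupState(present=present, onset_month=np.where(present, tau, 0.0),
                       removed=removed, E_remaining=E_remaining, use_slot2=removed)


# ---------------------------------------------------------------------------
# death resolution (spec contract; engine applies the same precedence inline)
# ---------------------------------------------------------------------------


def resolve_death(probs: dict, u: dict | None = None,
                  rng: np.random.Generator | None = None) -> str | None:
    """Resolve competing per-cycle death causes for one individual.

    ``probs`` maps cause -> monthly probability.  Causes are evaluated as
    independent Bernoulli draws; when several fire in the same cycle the
    documented precedence (other, lc, copd, cvd) decides the recorded cause.
    """
    fired = []
    for cause in CAUSES:
        p = probs.get(cause, 0.0)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {cause} outside [0, 1]")
        uu = (u[cause] if u is not None else rng.random())
        if uu < p:
            fired.append(cause)
    return fired[0] if fired else None


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def run_strategy(cohort: pd.DataFrame, strategy: StrategySpec,
                 params: ParameterSet, seed: int,
                 horizon_months: int | None = None,
                 record_ledger: bool = False) -> RunResult:
    """Simulate one cohort under one strategy; deterministic given the seed.

    ``horizon_months`` truncates the simulation (used by calibration); the
    default runs to the age-100 cap.  With ``record_ledger`` the per-cycle
    undiscounted cost and utility matrices are attached for audit.
    """
    params.require_valid()
    n = len(cohort)
    c, ut, sp, lc, cp, cv = (params.costs, params.utilities, params.screening,
                             params.lung_cancer, params.copd, params.cvd)

    age0 = cohort["age"].to_numpy(dtype=np.int32)
    male = (cohort["sex"].to_numpy() == "male")
    current0 = (cohort["smoking_status"].to_numpy() == "current")
    pack_years = cohort["pack_years"].to_numpy(dtype=float)
    fam = cohort["family_history_lc"].to_numpy(dtype=bool)
    prior_cvd = cohort["prior_cvd"].to_numpy(dtype=bool)
    prior_copd = cohort["prior_copd_dx"].to_numpy(dtype=bool)
    emph = np.asarray([EMPHYSEMA_LEVELS.index(x)
                       for x in cohort["emphysema_severity"]], dtype=np.int8)
    cac = np.asarray([CAC_LEVELS.index(x)
                      for x in cohort["cac_category"]], dtype=np.int8)
    chd_cur = cohort["chd_risk_annual"].to_numpy(dtype=float)
    chd_frm = cohort["chd_risk_annual_former"].to_numpy(dtype=float)
    str_cur = cohort["stroke_risk_annual"].to_numpy(dtype=float)
    str_frm = cohort["stroke_risk_annual_former"].to_numpy(dtype=float)
    lc6 = cohort["lc_risk_6y"].to_numpy(dtype=float)
    lc6_frm = cohort["lc_risk_6y_former"].to_numpy(dtype=float)

    cap_months = (params.sim.max_age - age0) * 12
    T_full = int(cap_months.max()) + 1  # include the forced terminal cycle
    T = T_full if horizon_months is None else min(horizon_months, T_full)
    n_rounds = ((sp.stop_age - sp.start_age) * 12) // max(strategy.interval_months, 1) + 1

    lat = draw_latents(n, T_full, n_rounds, params, seed)
    # onset hazard: monthly PLCO-risk hazard, rescaled so the lifetime
    # cumulative incidence matches the published aggregate (calibrated)
    onset_scale = lc.onset_hazard_scale
    lam_onset0 = -np.log1p(-lc6) / 72.0 * onset_scale
    wu = warmup(lam_onset0, params.sim.warmup_months, lat, params)

    vdt_act = np.where(wu.use_slot2, lat.vdt2, lat.vdt1)
    thr_act = np.where(wu.use_slot2, lat.thr2, lat.thr1)
    u_stage_act = np.where(wu.use_slot2, lat.u_stage2, lat.u_stage1)

    # attendance probabilities (per smoking status; re-looked-up on quitting)
    if strategy.screens:
        coeffs = params.attendance_coeffs or load_attendance_coeffs()
        prior_dx = prior_copd | prior_cvd
        p_att_cur = attendance_probability(age0, male, True, fam, prior_dx,
                                           pack_years, strategy, coeffs,
                                           sp.attendance_lo, sp.attendance_hi)
        p_att_frm = attendance_probability(age0, male, False, fam, prior_dx,
                                           pack_years, strategy, coeffs,
                                           sp.attendance_lo, sp.attendance_hi)
        # recentre to the (possibly PSA-sampled) mean attendance level
        shift = sp.attendance_mean - float(
            np.mean(np.where(current0, p_att_cur, p_att_frm)))
        p_att_cur = np.clip(p_att_cur + shift, sp.attendance_lo, sp.attendance_hi)
        p_att_frm = np.clip(p_att_frm + shift, sp.attendance_lo, sp.attendance_hi)

    # ---- mutable state ----------------------------------------------------
    alive = np.ones(n, dtype=bool)
    cause = np.full(n, -1, dtype=np.int8)
    death_t = np.full(n, -1, dtype=np.int32)
    present = wu.present.copy()
    tau = wu.onset_month.astype(float).copy()
    diagnosed = np.zeros(n, dtype=bool)
    dx_t = np.full(n, -1, dtype=np.int32)
    substage = np.full(n, -1, dtype=np.int8)
    group = np.full(n, -1, dtype=np.int8)
    cum_onset = np.zeros(n)
    E_rem = wu.E_remaining.copy()
    quit = np.zeros(n, dtype=bool)
    current = current0.copy()
    lam_lc = lam_onset0.copy()
    ever_att = np.zeros(n, dtype=bool)
    copd_dx = (prior_copd & (emph >= 1)).copy()
    copd_treated = copd_dx.copy()
    on_statin = prior_cvd & (lat.u_statin_bg < sp.background_statin_history)
    on_ace = prior_cvd & (lat.u_ace_bg < sp.background_ace_history)
    exac_hist = np.zeros((n, 12), dtype=np.int16)
    exac12 = np.zeros(n, dtype=np.int16)
    cum_oc = np.zeros(n)
    cum_lcd = np.zeros(n)
    cum_copd = np.zeros(n)
    cum_chd = np.zeros(n)
    cum_str = np.zeros(n)
    chd_idx = np.zeros(n, dtype=np.int16)
    str_idx = np.zeros(n, dtype=np.int16)
    next_chd = lat.chd_thresholds[:, 0].copy()
    next_str = lat.stroke_thresholds[:, 0].copy()
    last_stroke = np.full(n, -10**6, dtype=np.int32)
    last_chd = np.full(n, -10**6, dtype=np.int32)
    cost_total = np.zeros(n)
    qaly_total = np.zeros(n)

    # constants
    mt = params.mortality
    ages_grid = np.arange(0, params.sim.max_age + 2)
    p_oc_annual = np.clip(mt.other_cause_annual
                          * np.exp(mt.other_cause_log_slope
                                   * (ages_grid - mt.other_cause_ref_age)),
                          0.0, 0.999999)
    lam_oc_by_age = -np.log1p(-(1.0 - (1.0 - p_oc_annual) ** (1 / 12)))
    d0 = lc.start_diameter_mm
    dfc = (1.0 + params.sim.discount_rate_costs) ** (-np.arange(T) / 12.0)
    dfe = (1.0 + params.sim.discount_rate_effects) ** (-np.arange(T) / 12.0)
    exac_base = np.asarray(cp.annual_exacerbation_rate)[emph] / 12.0
    gom_c = np.asarray([lc.gompertz_c[s] for s in SUBSTAGES])
    gom_b = np.asarray([lc.gompertz_b[s] for s in SUBSTAGES])
    operable = np.asarray([s in lc.operable_substages for s in SUBSTAGES])
    type_cum = np.cumsum(cv.chd_type_probs)
    sub_to_group = np.asarray([SUBSTAGE_TO_GROUP[s] for s in SUBSTAGES], dtype=np.int8)
    gold_mult = np.asarray(ut.copd_gold)
    stage_mult = np.asarray(ut.lc_stage)
    copd_cost_m = np.asarray(c.copd_annual) / 12.0
    lc_month_cost = np.asarray([c.lc_monthly_stage_i_ii, c.lc_monthly_stage_i_ii,
                                c.lc_monthly_stage_iii, c.lc_monthly_stage_iv])
    lc_dur = np.asarray([c.lc_treatment_months_i_iii] * 3 + [c.lc_treatment_months_iv])
    min_sev = params.sim.copd_death_applies_from_severity

    # quit applied at simulation start for the no-participation pathway
    p_base, p_screen = params.cessation.p_base, max(params.cessation.p_screen,
                                                    params.cessation.p_base)
    quit0 = current & (lat.u_quit < p_base)
    quit |= quit0
    current[quit0] = False
    lam_lc[quit0] = -np.log1p(-lc6_frm[quit0]) / 72.0 * onset_scale

    K = {k: 0 for k in (
        "lc_deaths_10y", "copd_deaths_10y", "cvd_deaths_10y", "other_deaths_10y",
        "chd_type_deaths_10y", "moderate_exacerbations_lifetime",
        "severe_exacerbations_lifetime", "exacerbations_year1", "copd_dx_year1",
        "copd_dx_lifetime", "mi_10y", "cardiac_arrest_10y", "angina_10y",
        "strokes_10y", "lc_dx_10y", "lc_dx_lifetime", "false_positives",
        "true_positives", "scans_with_tumor", "scans_without_tumor",
        "screen_detected", "symptomatic_detected", "attended_scans", "invitations")}
    stage10 = np.zeros(4, dtype=np.int64)
    dx_diams: list = []
    lc_cases = int(present.sum())  # prevalent tumours at screening start

    ledger_cost = np.zeros((n, T), dtype=np.float32) if record_ledger else None
    ledger_util = np.zeros((n, T), dtype=np.float32) if record_ledger else None

    interval = strategy.interval_months

    for t in range(T):
        if not alive.any():
            break
        # (1) other-cause death; age cap forces the terminal transition
        cum_oc[alive] += lam_oc_by_age[age0[alive] + t // 12]
        die_oc = alive & ((cum_oc >= lat.E_oc) | (t >= cap_months))
        if die_oc.any():
            cause[die_oc] = 0
            death_t[die_oc] = t
            alive[die_oc] = False
            if t < 120:
                K["other_deaths_10y"] += int(die_oc.sum())
        act = alive.copy()
        if not act.any():
            break
        cost_t = np.zeros(n)

        # (2) tumour onset and growth
        no_t = act & ~present
        cum_onset[no_t] += lam_lc[no_t]
        onset = no_t & (cum_onset >= E_rem)
        if onset.any():
            present[onset] = True
            tau[onset] = t
            lc_cases += int(onset.sum())
        und = act & present & ~diagnosed
        d_full = np.zeros(n)
        if und.any():
            d_full[und] = d0 * np.exp2((t - tau[und]) * DAYS_PER_MONTH
                                       / (3.0 * vdt_act[und]))

        # (3) screening round
        if strategy.screens and t % interval == 0:
            k_round = t // interval
            if k_round < n_rounds:
                age_y = age0 + t // 12
                elig = act & ~diagnosed & (age_y <= sp.stop_age)
                if elig.any():
                    cost_t[elig] += c.invitation
                    K["invitations"] += int(elig.sum())
                    p_att = np.where(current, p_att_cur, p_att_frm)
                    att = elig & (lat.u_att[:, k_round] < p_att)
                    cost_t[att] += c.ldct_scan
                    K["attended_scans"] += int(att.sum())
                    nb = att & ~ever_att
                    ever_att |= att
                    # baseline-only COPD/CVD evaluation
                    if "COPD" in strategy.diseases and nb.any():
                        ref = nb & (emph >= 2) & ~copd_dx
                        copd_dx |= ref
                        copd_treated |= ref
                        K["copd_dx_lifetime"] += int(ref.sum())
                        if t < 12:
                            K["copd_dx_year1"] += int(ref.sum())
                    if "CVD" in strategy.diseases and nb.any():
                        refc = nb & (cac >= 2)
                        new_st = refc & (lat.u_statin < sp.statin_prop)
                        p_ace = np.where(prior_cvd, sp.ace_prop_history,
                                         sp.ace_prop_no_history)
                        new_ace = refc & (lat.u_ace < p_ace)
                        on_statin |= new_st
                        on_ace |= new_ace
                    # screening-linked smoking cessation (once, result-independent)
                    qn = nb & current & (lat.u_quit < p_screen)
                    if qn.any():
                        quit |= qn
                        current[qn] = False
                        lam_lc[qn] = -np.log1p(-lc6_frm[qn]) / 72.0 * onset_scale
                    # LC test
                    wt = att & present & ~diagnosed
                    K["scans_with_tumor"] += int(wt.sum())
                    sens = np.zeros(n)
                    if wt.any():
                        sd = d_full[wt]
                        sens[wt] = np.where(
                            sd < sp.sens_d_lo, 0.0,
                            np.where(sd >= sp.sens_d_hi, 1.0,
                                     np.clip(sp.sens_slope * sd + sp.sens_intercept,
                                             0.0, 1.0)))
                    tp = wt & (lat.u_test[:, k_round] < sens)
                    no_tum = att & ~wt
                    K["scans_without_tumor"] += int(no_tum.sum())
                    fp = no_tum & (lat.u_test[:, k_round] < 1.0 - sp.specificity)
                    K["false_positives"] += int(fp.sum())
                    K["true_positives"] += int(tp.sum())
                    pos = tp | fp
                    if pos.any():
                        cost_t[pos] += c.diagnosis
                    if tp.any():
                        _diagnose(tp, d_full, t, lc, u_stage_act, substage, group,
                                  diagnosed, dx_t, sub_to_group, operable, cost_t,
                                  c, K, stage10, dx_diams)
                        K["screen_detected"] += int(tp.sum())

        # (4) symptomatic detection
        und = act & present & ~diagnosed
        sym = und & (d_full >= thr_act)
        if sym.any():
            cost_t[sym] += c.diagnosis
            _diagnose(sym, d_full, t, lc, u_stage_act, substage, group,
                      diagnosed, dx_t, sub_to_group, operable, cost_t, c, K,
                      stage10, dx_diams)
            K["symptomatic_detected"] += int(sym.sum())

        # (5) COPD exacerbations
        me = act & (emph >= 1)
        k_ex = np.zeros(n, dtype=np.int16)
        sev_ex = np.zeros(n, dtype=np.int16)
        if me.any():
            mu = exac_base[me]
            mu = mu * np.where(copd_treated[me], cp.rr_exacerbation_treated, 1.0)
            mu = mu * np.where(quit[me], cp.rr_exacerbation_quit, 1.0)
            k_ex[me] = _poisson_icdf(lat.U_exac[me, t].astype(float), mu)
            sev_ex = _binom_split(lat.U_sev[:, t].astype(float), k_ex,
                                  cp.severe_exacerbation_fraction)
            mod_ex = k_ex - sev_ex
            tot = int(k_ex.sum())
            K["moderate_exacerbations_lifetime"] += int(mod_ex.sum())
            K["severe_exacerbations_lifetime"] += int(sev_ex.sum())
            if t < 12:
                K["exacerbations_year1"] += tot
            cost_t += k_ex * c.exacerbation
            nd = me & ~copd_dx & (k_ex > 0)
            if nd.any():
                p_dx = -np.expm1(np.log1p(-cp.dx_prob_per_exacerbation) * k_ex[nd])
                dx = np.zeros(n, dtype=bool)
                dx[nd] = lat.U_copddx[nd, t].astype(float) < p_dx
                copd_dx |= dx
                copd_treated |= dx
                K["copd_dx_lifetime"] += int(dx.sum())
                if t < 12:
                    K["copd_dx_year1"] += int(dx.sum())
        hr_k = exac12.copy()  # prior-12-month window, excluding this cycle
        exac12 += k_ex - exac_hist[:, t % 12]
        exac_hist[:, t % 12] = k_ex

        # (6) CVD events
        pending_cvd = np.zeros(n, dtype=bool)
        chd_death_type = np.zeros(n, dtype=bool)
        chd_ann = np.where(quit, chd_frm, chd_cur).copy()
        chd_ann *= np.where(on_statin, cv.rr_statin_chd, 1.0)
        chd_ann *= np.where(on_ace, cv.rr_ace_chd, 1.0)
        cum_chd[act] += -np.log1p(-chd_ann[act]) / 12.0
        fire = act & (cum_chd >= next_chd) & (chd_idx < _K_CHD)
        if fire.any():
            idx = np.where(fire)[0]
            uu = lat.u_chd_type[idx, chd_idx[idx]]
            typ = np.searchsorted(type_cum, uu)  # 0 mi, 1 angina, 2 chd death, 3 arrest
            mi_i = idx[typ == 0]
            ang_i = idx[typ == 1]
            cd_i = idx[typ == 2]
            ar_i = idx[typ == 3]
            cost_t[mi_i] += c.mi
            cost_t[ang_i] += c.cardiac_arrest_or_angina
            cost_t[ar_i] += c.cardiac_arrest_or_angina
            if t < 120:
                K["mi_10y"] += len(mi_i)
                K["angina_10y"] += len(ang_i)
                K["cardiac_arrest_10y"] += len(ar_i)
            pending_cvd[cd_i] = True
            chd_death_type[cd_i] = True
            ar_fatal = ar_i[lat.u_chd_fatal[ar_i, chd_idx[ar_i]]
                            < cv.cardiac_arrest_fatality]
            pending_cvd[ar_fatal] = True
            chd_death_type[ar_fatal] = True
            surv_ev = np.concatenate([mi_i, ang_i, np.setdiff1d(ar_i, ar_fatal)])
            last_chd[surv_ev] = t
            chd_idx[idx] += 1
            nxt = np.minimum(chd_idx[idx], _K_CHD - 1)
            next_chd[idx] = lat.chd_thresholds[idx, nxt]

        str_ann = np.where(quit, str_frm, str_cur).copy()
        str_ann *= np.where(on_statin, cv.rr_statin_stroke, 1.0)
        str_ann *= np.where(on_ace, cv.rr_ace_stroke, 1.0)
        cum_str[act] += -np.log1p(-str_ann[act]) / 12.0
        sfire = act & (cum_str >= next_str) & (str_idx < _K_STR)
        if sfire.any():
            idx = np.where(sfire)[0]
            if t < 120:
                K["strokes_10y"] += len(idx)
            fatal = lat.u_stroke_fatal[idx, str_idx[idx]] < cv.stroke_fatality
            pending_cvd[idx[fatal]] = True
            last_stroke[idx[~fatal]] = t
            str_idx[idx] += 1
            nxt = np.minimum(str_idx[idx], _K_STR - 1)
            next_str[idx] = lat.stroke_thresholds[idx, nxt]

        # (7) disease-specific deaths, documented precedence LC > COPD > CVD
        dxd = act & diagnosed
        fire_lc = np.zeros(n, dtype=bool)
        if dxd.any():
            m = (t - dx_t[dxd]).astype(float)
            cc, bb = gom_c[substage[dxd]], gom_b[substage[dxd]]
            with np.errstate(over="ignore"):
                H = np.where(cc == 0.0, bb,
                             bb * (np.exp(cc * (m + 1)) - np.exp(cc * m))
                             / np.where(cc == 0.0, 1.0, cc))
            cum_lcd[dxd] += H
            fire_lc = dxd & (cum_lcd >= lat.E_lc)
        ce = act & (emph >= min_sev)
        fire_copd = np.zeros(n, dtype=bool)
        if ce.any() and cp.base_monthly_hazard > 0:
            hr = np.where(hr_k >= 3, cp.hr_mortality_3plus,
                          np.where(hr_k >= 1, cp.hr_mortality_1_2, 1.0))
            cum_copd[ce] += cp.base_monthly_hazard * hr[ce]
            fire_copd = ce & (cum_copd >= lat.E_copd)
        die_lc = fire_lc
        die_copd = fire_copd & ~die_lc
        die_cvd = pending_cvd & act & ~die_lc & ~die_copd
        for mask, code, key in ((die_lc, 1, "lc_deaths_10y"),
                                (die_copd, 2, "copd_deaths_10y"),
                                (die_cvd, 3, "cvd_deaths_10y")):
            if mask.any():
                cause[mask] = code
                death_t[mask] = t
                alive[mask] = False
                if t < 120:
                    K[key] += int(mask.sum())
        if t < 120:
            K["chd_type_deaths_10y"] += int((die_cvd & chd_death_type).sum())

        # (8) accrual: ongoing monthly costs for everyone active this cycle,
        # utility only for cycle survivors
        treat = dxd & ((t - dx_t) < lc_dur[np.maximum(group, 0)])
        cost_t[treat] += lc_month_cost[np.maximum(group, 0)][treat]
        cm = act & copd_dx & (emph >= 1)
        cost_t[cm] += copd_cost_m[emph[cm] - 1]
        cost_t[act & on_statin] += c.statin_annual / 12.0
        cost_t[act & on_ace] += c.ace_annual / 12.0
        ds = t - last_stroke
        in1 = act & (ds >= 0) & (ds <= 5)
        in2 = act & (ds >= 6) & (ds <= 12)
        cost_t[in1] += c.stroke_monthly_1_6
        cost_t[in2] += c.stroke_monthly_7_13

        cost_total += cost_t * dfc[t]

        surv = alive
        age_y = age0 + t // 12
        w = np.where(age_y <= 60, ut.baseline_le60,
                     np.where(age_y <= 70, ut.baseline_60_70, ut.baseline_gt70))
        # GOLD disutility follows the underlying emphysema grade, not diagnosis
        w = w * np.where(emph >= 1, gold_mult[np.maximum(emph - 1, 0)], 1.0)
        w = w * np.where(diagnosed, stage_mult[np.maximum(group, 0)], 1.0)
        w = w * np.where(sev_ex > 0, ut.exacerbation_severe,
                         np.where(k_ex > 0, ut.exacerbation_moderate, 1.0))
        dsm = t - last_stroke
        w = w * np.where(dsm == 0, ut.stroke_first_month,
                         np.where((dsm > 0) & (last_stroke >= 0), ut.stroke_after, 1.0))
        dcm = t - last_chd
        w = w * np.where(dcm == 0, ut.chd_first_month,
                         np.where((dcm > 0) & (last_chd >= 0), ut.chd_after, 1.0))
        w = np.where(surv, w, 0.0)
        qaly_total += w / 12.0 * dfe[t]

        if record_ledger:
            ledger_cost[:, t] = cost_t
            ledger_util[:, t] = w

    # ---- results ----------------------------------------------------------
    deaths_10y = {k: K[f"{k}_deaths_10y"] for k in ("lc", "copd", "cvd", "other")}
    counts = dict(K)
    counts["total_deaths_10y"] = sum(deaths_10y.values())
    counts["copd_cases"] = int((emph >= 1).sum())
    counts["quitters"] = int(quit.sum())
    counts["smokers_at_start"] = int(current0.sum())
    counts["statin_ever"] = int(on_statin.sum())
    counts["ace_ever"] = int(on_ace.sum())
    counts["lc_cases_lifetime"] = lc_cases
    counts["lc_dx_lifetime"] = int(diagnosed.sum())
    counts["lc_dx_10y"] = int(((dx_t >= 0) & (dx_t < 120)).sum())
    counts["deaths_total"] = int((cause >= 0).sum())

    tot_stage = stage10.sum()
    stage_dist = {g: (100.0 * stage10[i] / tot_stage if tot_stage else 0.0)
                  for i, g in enumerate(STAGE_GROUPS)}

    per_ind = None
    if record_ledger:
        per_ind = pd.DataFrame({
            "id": cohort["id"].to_numpy(),
            "cost": cost_total, "qaly": qaly_total,
            "cause": np.asarray(["none", *CAUSES])[cause + 1],
            "death_month": death_t,
        })

    return RunResult(
        strategy=strategy.name, n_individuals=n, seed=seed,
        mean_cost=float(cost_total.mean()), mean_qaly=float(qaly_total.mean()),
        counts=counts, stage_distribution_10y=stage_dist,
        detected_diameters_10y=(np.concatenate(dx_diams) if dx_diams
                                else np.empty(0)),
        per_individual=per_ind,
        ledger=(None if not record_ledger else
                {"cost": ledger_cost, "utility": ledger_util,
                 "df_cost": dfc, "df_effect": dfe,
                 "cost_total": cost_total, "qaly_total": qaly_total}),
    )


def _diagnose(mask, d_full, t, lc, u_stage_act, substage, group, diagnosed,
              dx_t, sub_to_group, operable, cost_t, costs, K, stage10, dx_diams):
    from .natural_history import stage_at_detection
    d = d_full[mask]
    if t < 120:
        dx_diams.append(d)
    sub = stage_at_detection(d, lc, u_stage_act[mask])
    substage[mask] = sub
    group[mask] = sub_to_group[sub]
    diagnosed[mask] = True
    dx_t[mask] = t
    op = np.zeros(len(d_full), dtype=bool)
    op[mask] = operable[sub]
    cost_t[op] += costs.lc_surgery_onceoff
    K["lc_dx_lifetime"] += int(mask.sum())
    if t < 120:
        K["lc_dx_10y"] += int(mask.sum())
        np.add.at(stage10, sub_to_group[sub], 1)


def intermediate_outcomes(result: RunResult) -> dict:
    """Table-style intermediate outcomes for one run (counts + stage %)."""
    out = dict(result.counts)
    out.update({f"stage_{g}_pct_10y": v
                for g, v in result.stage_distribution_10y.items()})
    return out


def run_strategies(cohort: pd.DataFrame, strategies: list[StrategySpec],
                   params: ParameterSet, seed: int,
                   horizon_months: int | None = None) -> list[RunResult]:
    """Run several strategies with common random numbers (same seed/cohort)."""
    return [run_strategy(cohort, s, params, seed, horizon_months=horizon_months)
            for s in strategies]
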