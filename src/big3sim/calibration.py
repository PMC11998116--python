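"""Calibration of under-determined natural-history parameters.

Two quantities in the model cannot be read off published tables and are fitted
to targets instead:

* the diameter-indexed stage-at-detection model (ordered-logit slope and
  cutpoints), calibrated to the diagnosed stage distributions with and
  without LC screening over the first ten simulated years; and
* the COPD base monthly mortality hazard, calibrated to the 10-year COPD
  death count per 10,000 in the unscreened arm.

The stage model only affects survival *after* diagnosis, never which tumours
are detected when, so the set of detection diameters in a 10-year run is
independent of the stage parameters.  Calibration exploits this: one
simulation per arm (common random numbers) collects the empirical detection
diameters, after which stage distributions for any candidate (slope,
cutpoints) are expectations over those diameters and can be fitted without
further simulation.  For a given slope the three cutpoints solve the
no-screening targets exactly (three monotone root-finds); the slope is then
fitted to the screening-arm targets by a bounded derivative-free search.
Warm-up length and the self-detection mean can be freed as outer parameters,
in which case the diameter sets are re-simulated per candidate.  Calibration
is deterministic given (targets, seed, budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .params import ParameterSet, STAGE_GROUPS
from .population import CohortConfig, generate_cohort
from .screening import StrategySpec
from .engine import run_strategy


@dataclass
class CalibrationTargets:
    """Targets for stage-model and COPD-mortality calibration (percent scale)."""

    stage_no_screening: tuple[float, ...] = (37.5, 8.8, 19.1, 34.7)
    stage_lc_screening: tuple[float, ...] = (70.3, 6.3, 11.3, 12.2)
    # fraction of round-1 attended scans yielding a screen-detected LC;
    # not printed in the source — configured (trial-derived) value, optional
    first_round_detection_rate: float | None = None
    copd_deaths_10y_per_10k: float = 130.0

    def validate(self) -> list[str]:
        errs = []
        for nm in ("stage_no_screening", "stage_lc_screening"):
            v = getattr(self, nm)
            if len(v) != 4:
                errs.append(f"{nm}: need 4 stage-group percentages")
            elif abs(sum(v) - 100.0) > 0.2:
                errs.append(f"{nm}: percentages sum to {sum(v):.2f}, not 100")
        return errs


@dataclass
class CalibrationResult:
    fitted: dict
    objective: float
    residuals: dict
    n_evals: int
    seed: int
    converged: bool
    params: ParameterSet | None = None
    history: list = field(default_factory=list)


FREE_PARAMS = ("stage_slope", "self_detect_mean", "warmup_months")
_SLOPE_BOUNDS = (0.5, 8.0)


# ---------------------------------------------------------------------------
# stage-model fitting against detection-diameter samples
# ---------------------------------------------------------------------------


def _expected_stage_pct(diameters: np.ndarray, slope: float, cuts) -> np.ndarray:
    """Expected stage-group distribution (%) over detected diameters."""
    eta = slope * np.log(diameters)
    cum = expit(np.asarray(cuts)[None, :] - eta[:, None]).mean(axis=0)
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    return 100.0 * probs


def _solve_cutpoints_on(diameters: np.ndarray, slope: float,
                        stage_targets_pct) -> tuple:
    """Cutpoints matching cumulative stage targets over given diameters."""
    eta = slope * np.log(diameters)
    cums = np.cumsum(np.asarray(stage_targets_pct) / 100.0)[:3]
    lo, hi = float(eta.min() - 40), float(eta.max() + 40)
    cuts, prev = [], lo
    for q in cums:
        ck = optimize.brentq(
            lambda c: float(np.mean(expit(c - eta))) - q, prev, hi, xtol=1e-9)
        cuts.append(ck)
        prev = ck  # cumulative targets increase, so cutpoints are ordered
    return tuple(cuts)


def _detection_diameter_grid(params: ParameterSet, m: int = 512) -> np.ndarray:
    """Quadrature grid over the symptomatic self-detection distribution."""
    lc = params.lung_cancer
    scale = 1.0 / lc.self_detect_rate
    fcap = stats.gamma.cdf(lc.self_detect_cap_mm, lc.self_detect_shape, scale=scale)
    u = (np.arange(m) + 0.5) / m
    return stats.gamma.ppf(u * fcap, lc.self_detect_shape, scale=scale)


def solve_stage_cutpoints(params: ParameterSet, slope: float,
                          stage_targets_pct=(37.5, 8.8, 19.1, 34.7)) -> tuple:
    """Analytic cutpoints vs the self-detection diameter distribution.

    Uses the truncated-gamma quadrature grid as the detection-diameter law;
    a good initialisation (simulation-based fitting refines it against the
    empirical detection diameters, which include prevalent-pool and
    window-selection effects).
    """
    return _solve_cutpoints_on(_detection_diameter_grid(params), slope,
                               stage_targets_pct)


# ---------------------------------------------------------------------------
# simulation-based calibration
# ---------------------------------------------------------------------------


def _simulate_diameters(params: ParameterSet, cohort, seed: int):
    r_ns = run_strategy(cohort, StrategySpec(), params, seed, horizon_months=120)
    r_scr = run_strategy(cohort, StrategySpec(diseases=frozenset({"LC"})),
                         params, seed, horizon_months=120)
    return r_ns.detected_diameters_10y, r_scr.detected_diameters_10y


def _fit_stage_model(d_ns: np.ndarray, d_scr: np.ndarray,
                     targets: CalibrationTargets, budget: int):
    """(slope, cutpoints, objective, n_evals) fitted to both arms."""
    evals = {"n": 0}

    def obj(slope: float) -> float:
        evals["n"] += 1
        cuts = _solve_cutpoints_on(d_ns, slope, targets.stage_no_screening)
        pred = _expected_stage_pct(d_scr, slope, cuts)
        return float(np.sum((pred - np.asarray(targets.stage_lc_screening)) ** 2))

    res = optimize.minimize_scalar(obj, bounds=_SLOPE_BOUNDS, method="bounded",
                                   options={"maxiter": max(budget, 5),
                                            "xatol": 5e-3})
    slope = float(res.x)
    cuts = _solve_cutpoints_on(d_ns, slope, targets.stage_no_screening)
    return slope, cuts, float(res.fun), evals["n"]


def calibrate(targets: CalibrationTargets, params: ParameterSet,
              free_params: tuple[str, ...] = ("stage_slope",),
              budget: int = 40, seed: int = 0,
              cohort_config: CohortConfig | None = None) -> CalibrationResult:
    """Fit the requested free parameters to the stage-distribution targets.

    ``free_params`` is a subset of ``("stage_slope", "self_detect_mean",
    "warmup_months")``.  With an empty tuple the objective is evaluated once
    and nothing changes; with only ``stage_slope`` two simulations suffice
    (see module docstring); freeing warm-up or the self-detection mean nests
    the stage fit inside a Nelder-Mead over the outer parameters.  Returns
    best-so-far when the budget is exhausted.
    """
    errs = targets.validate()
    if errs:
        raise ValueError("invalid calibration targets:\n  " + "\n  ".join(errs))
    unknown = set(free_params) - set(FREE_PARAMS)
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}; "
                         f"choose from {FREE_PARAMS}")
    cfg = cohort_config or CohortConfig(n_individuals=4000, seed=seed)
    base = params.copy()
    cohort = generate_cohort(cfg, base, seed=seed)
    history: list = []
    n_evals = 0

    def apply_outer(theta: dict) -> ParameterSet:
        p = base.copy()
        if "self_detect_mean" in theta:
            p.lung_cancer.self_detect_rate = (
                p.lung_cancer.self_detect_shape / max(theta["self_detect_mean"], 1.0))
        if "warmup_months" in theta:
            p.sim.warmup_months = max(int(round(theta["warmup_months"])), 0)
        return p

    def stage_fit_for(theta: dict):
        nonlocal n_evals
        p = apply_outer(theta)
        d_ns, d_scr = _simulate_diameters(p, cohort, seed)
        n_evals += 2
        if len(d_ns) < 20 or len(d_scr) < 20:
            return p, np.inf, {}
        if "stage_slope" in free_params or not free_params:
            slope, cuts, obj, ne = _fit_stage_model(d_ns, d_scr, targets, budget)
            n_evals += ne
        else:
            slope = p.lung_cancer.stage_slope
            cuts = _solve_cutpoints_on(d_ns, slope, targets.stage_no_screening)
            obj = float(np.sum((_expected_stage_pct(d_scr, slope, cuts)
                                - np.asarray(targets.stage_lc_screening)) ** 2))
        p.lung_cancer.stage_slope = slope
        p.lung_cancer.stage_cutpoints = cuts
        res = {}
        for key, d, tgt in (("no_screening", d_ns, targets.stage_no_screening),
                            ("lc_screening", d_scr, targets.stage_lc_screening)):
            pred = _expected_stage_pct(d, slope, cuts)
            for i, g in enumerate(STAGE_GROUPS):
                res[f"stage_{g}_{key}"] = float(pred[i] - tgt[i])
        history.append((dict(theta), slope, obj))
        return p, obj, res

    if not free_params:
        p0 = apply_outer({})
        d_ns, d_scr = _simulate_diameters(p0, cohort, seed)
        n_evals += 2
        slope = p0.lung_cancer.stage_slope
        cuts = p0.lung_cancer.stage_cutpoints
        res = {}
        for key, d, tgt in (("no_screening", d_ns, targets.stage_no_screening),
                            ("lc_screening", d_scr, targets.stage_lc_screening)):
            pred = _expected_stage_pct(d, slope, cuts)
            for i, g in enumerate(STAGE_GROUPS):
                res[f"stage_{g}_{key}"] = float(pred[i] - tgt[i])
        obj = float(sum(v * v for v in res.values()))
        return CalibrationResult(fitted={}, objective=obj, residuals=res,
                                 n_evals=n_evals, seed=seed, converged=True,
                                 params=p0, history=history)

    outer = [f for f in free_params if f != "stage_slope"]
    if not outer:
        p, obj, res = stage_fit_for({})
        return CalibrationResult(
            fitted={"stage_slope": p.lung_cancer.stage_slope,
                    "stage_cutpoints": p.lung_cancer.stage_cutpoints},
            objective=obj, residuals=res, n_evals=n_evals, seed=seed,
            converged=np.isfinite(obj), params=p, history=history)

    best = {"obj": np.inf, "theta": {}, "params": None, "res": {}}

    def fun(x):
        theta = dict(zip(outer, np.atleast_1d(x)))
        p, obj, res = stage_fit_for(theta)
        if obj < best["obj"]:
            best.update(obj=obj, theta=theta, params=p, res=res)
        return obj

    x0 = []
    for name in outer:
        x0.append(base.lung_cancer.self_detect_shape / base.lung_cancer.self_detect_rate
                  if name == "self_detect_mean" else float(base.sim.warmup_months))
    optimize.minimize(fun, np.asarray(x0, dtype=float), method="Nelder-Mead",
                      options={"maxfev": max(budget // 4, 3), "xatol": 1.0,
                               "fatol": 0.5})
    fitted = dict(best["theta"])
    if best["params"] is not None:
        fitted["stage_slope"] = best["params"].lung_cancer.stage_slope
    return CalibrationResult(fitted=fitted, objective=best["obj"],
                             residuals=best["res"], n_evals=n_evals, seed=seed,
                             converged=np.isfinite(best["obj"]),
                             params=best["params"], history=history)


def calibrate_lc_onset_scale(params: ParameterSet,
                             cohort_config: CohortConfig | None = None,
                             seed: int = 0, n_iter: int = 3,
                             target: float | None = None) -> float:
    """Onset-hazard scale matching the lifetime cumulative LC incidence.

    The 6-year risk extrapolated as a flat lifetime hazard overshoots the
    published lifetime aggregate; iterative proportional fitting on the log
    survival scale (hazard-linear, common random numbers) finds the scale.
    """
    tgt = params.lung_cancer.cumulative_incidence_lifetime if target is None \
        else target
    if not 0 < tgt < 1:
        raise ValueError("lifetime incidence target must be in (0, 1)")
    cfg = cohort_config or CohortConfig(n_individuals=5000, seed=seed)
    p = params.copy()
    cohort = generate_cohort(cfg, p, seed=seed)
    scale = p.lung_cancer.onset_hazard_scale or 1.0
    for _ in range(n_iter):
        p.lung_cancer.onset_hazard_scale = scale
        rr = run_strategy(cohort, StrategySpec(), p, seed)
        inc = rr.counts["lc_cases_lifetime"] / cfg.n_individuals
        if inc <= 0 or inc >= 1:
            scale *= 2.0 if inc <= 0 else 0.5
            continue
        scale *= np.log1p(-tgt) / np.log1p(-inc)
    return float(scale)


def calibrate_copd_base_mortality(target_10y_deaths_per_10k: float,
                                  params: ParameterSet,
                                  cohort_config: CohortConfig | None = None,
                                  seed: int = 0, n_iter: int = 3) -> float:
    """Monthly base COPD death hazard matching a 10-year death-count target.

    Iterative proportional fitting on the (nearly linear) hazard-to-count map
    with common random numbers; a target of 0 returns hazard 0 exactly.
    """
    if target_10y_deaths_per_10k < 0:
        raise ValueError("target must be >= 0")
    if target_10y_deaths_per_10k == 0:
        return 0.0
    cfg = cohort_config or CohortConfig(n_individuals=5000, seed=seed)
    p = params.copy()
    cohort = generate_cohort(cfg, p, seed=seed)
    scale = cfg.n_individuals / 10_000.0
    h = p.copd.base_monthly_hazard or 1e-4
    for _ in range(n_iter):
        p.copd.base_monthly_hazard = h
        rr = run_strategy(cohort, StrategySpec(), p, seed, horizon_months=120)
        deaths = rr.counts["copd_deaths_10y"] / scale
        if deaths <= 0:
            h *= 2.0
            continue
        h *= target_10y_deaths_per_10k / deaths
    return float(h)
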