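"""Screening strategies, attendance, LDCT test performance and referral.

A strategy names the subset of {LC, COPD, CVD} screened with one annual LDCT
between ages 55 and 74; lung cancer is always part of any screening strategy
(COPD and CVD are add-on readings of the same scan).  Attendance is predicted
per strategy by an independent logistic model, so an individual may attend LC
screening but decline Big-3.  The LDCT detects lung tumours with a
diameter-dependent piecewise-linear sensitivity and a fixed specificity;
emphysema and coronary-calcium findings are evaluated at the baseline round
only and trigger COPD evaluation / preventative CVD treatment referrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .params import ParameterSet, ParameterError

DISEASES = ("LC", "COPD", "CVD")

STRATEGY_NAMES = {
    frozenset(): "No screening",
    frozenset({"LC"}): "LC",
    frozenset({"LC", "COPD"}): "LC+COPD",
    frozenset({"LC", "CVD"}): "LC+CVD",
    frozenset({"LC", "COPD", "CVD"}): "Big-3",
}


@dataclass(frozen=True)
class StrategySpec:
    """One screening strategy: which diseases, interval and age window."""

    diseases: frozenset = frozenset()
    interval_months: int = 12
    start_age: int = 55
    stop_age: int = 74
    label: str | None = None

    def __post_init__(self):
        bad = set(self.diseases) - set(DISEASES)
        if bad:
            raise ParameterError(f"unknown diseases in strategy: {sorted(bad)}")
        if self.diseases and "LC" not in self.diseases:
            raise ParameterError("COPD/CVD screening are add-ons: LC must be screened")
        if self.interval_months <= 0:
            raise ParameterError("interval_months must be positive")

    @property
    def screens(self) -> bool:
        return bool(self.diseases)

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return STRATEGY_NAMES.get(frozenset(self.diseases),
                                  "+".join(sorted(self.diseases)))

    @classmethod
    def from_name(cls, name: str) -> "StrategySpec":
        key = name.strip().lower().replace(" ", "")
        table = {
            "none": frozenset(), "noscreening": frozenset(),
            "no-screening": frozenset(),
            "lc": frozenset({"LC"}),
            "lc+copd": frozenset({"LC", "COPD"}),
            "lc+cvd": frozenset({"LC", "CVD"}),
            "big-3": frozenset(DISEASES), "big3": frozenset(DISEASES),
            "lc+copd+cvd": frozenset(DISEASES),
        }
        if key not in table:
            raise ParameterError(f"unknown strategy {name!r}; use one of "
                                 "none, LC, LC+COPD, LC+CVD, Big-3")
        return cls(diseases=table[key])


def default_strategies() -> list[StrategySpec]:
    """The five compared strategies, in the conventional order."""
    return [StrategySpec(diseases=d) for d in (
        frozenset(), frozenset({"LC"}), frozenset({"LC", "COPD"}),
        frozenset({"LC", "CVD"}), frozenset(DISEASES))]


# ---------------------------------------------------------------------------
# attendance
# ---------------------------------------------------------------------------


def _attendance_key(strategy: StrategySpec) -> str:
    key = STRATEGY_NAMES.get(frozenset(strategy.diseases))
    if key is None or key == "No screening":
        raise ParameterError(f"no attendance model for strategy {strategy.name!r}")
    return key


def attendance_probability(age, male, current_smoker, family_history_lc,
                           prior_dx, pack_years, strategy: StrategySpec,
                           coeffs_by_strategy: dict,
                           lo: float = 0.63, hi: float = 0.974) -> np.ndarray:
    """Per-round screening participation probability for one strategy.

    Logistic in age, sex, smoking status, family history of LC, prior
    COPD-or-CVD diagnosis, pack-years and the published interactions, clipped
    to the published attainable range [lo, hi].  Accepts scalars or arrays.
    """
    key = _attendance_key(strategy)
    if key not in coeffs_by_strategy:
        raise ParameterError(f"attendance coefficients missing strategy {key!r}")
    c = coeffs_by_strategy[key]
    z_age = (np.asarray(age, dtype=float) - 61.0) / 5.7
    z_py = (np.asarray(pack_years, dtype=float) - 48.0) / 20.0
    cur = np.asarray(current_smoker, dtype=float)
    pdx = np.asarray(prior_dx, dtype=float)
    lp = (c["intercept"]
          + c["z_age"] * z_age
          + c["male"] * np.asarray(male, dtype=float)
          + c["current_smoker"] * cur
          + c["family_history_lc"] * np.asarray(family_history_lc, dtype=float)
          + c["prior_dx"] * pdx
          + c["z_pack_years"] * z_py
          + c["current_x_prior_dx"] * cur * pdx
          + c["z_age_x_z_pack_years"] * z_age * z_py)
    return np.clip(expit(lp), lo, hi)


def intercept_only_coeffs(mean: float = 0.75) -> dict:
    """Coefficient table with every slope zero (all strategies identical)."""
    base = {"intercept": float(logit(mean)), "z_age": 0.0, "male": 0.0,
            "current_smoker": 0.0, "family_history_lc": 0.0, "prior_dx": 0.0,
            "z_pack_years": 0.0, "current_x_prior_dx": 0.0,
            "z_age_x_z_pack_years": 0.0}
    return {k: dict(base) for k in ("LC", "LC+COPD", "LC+CVD", "Big-3")}


# ---------------------------------------------------------------------------
# LDCT test performance
# ---------------------------------------------------------------------------


def ldct_sensitivity(diameter_mm, params: ParameterSet | None = None):
    """Per-scan sensitivity for a tumour of the given diameter (mm).

    Piecewise linear: 0 below 3 mm, 0.5*d - 1.5 on [3, 5) and 1 at >= 5 mm
    with the default breakpoints; continuous at both breakpoints.
    """
    s = (params or _DEFAULTS).screening
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be >= 0")
    out = np.clip(s.sens_slope * d + s.sens_intercept, 0.0, 1.0)
    out = np.where(d < s.sens_d_lo, 0.0, np.where(d >= s.sens_d_hi, 1.0, out))
    return float(out) if np.isscalar(diameter_mm) else out


# ---------------------------------------------------------------------------
# referral and cessation
# ---------------------------------------------------------------------------


def cvd_referral(prior_cvd, u_statin, u_ace, params: ParameterSet):
    """Preventative-treatment assignment after a moderate/severe CAC finding.

    Statins are assigned with the configured proportion; ACE inhibitors with
    the published 22% among individuals without a CVD history (separate
    configurable proportion with history).  Assignment persists for life.
    Returns (statin, ace) boolean arrays.
    """
    s = params.screening
    prior = np.asarray(prior_cvd, dtype=bool)
    statin = np.asarray(u_statin) < s.statin_prop
    p_ace = np.where(prior, s.ace_prop_history, s.ace_prop_no_history)
    ace = np.asarray(u_ace) < p_ace
    return statin, ace


def cessation_probabilities(params: ParameterSet) -> tuple[float, float]:
    """(p_without, p_with_participation); the latter never smaller."""
    ce = params.cessation
    return ce.p_base, max(ce.p_screen, ce.p_base)


def symptomatic_detection_cycle(d0_mm, vdt_days, threshold_mm,
                                onset_month: float) -> float:
    """First cycle index at which the growing tumour reaches its threshold.

    Inverts the growth law; returns inf if the threshold is never reached
    (non-growing limit).
    """
    from .natural_history import diameter_to_days
    from .params import DAYS_PER_MONTH
    if threshold_mm <= d0_mm:
        return float(np.ceil(onset_month))
    days = diameter_to_days(d0_mm, vdt_days, threshold_mm)
    return float(np.ceil(onset_month + days / DAYS_PER_MONTH))


_DEFAULTS = ParameterSet()
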