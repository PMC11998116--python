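"""Latent disease dynamics per monthly cycle.

Lung tumours appear at a fixed starting diameter, grow exponentially in volume
with an individually sampled volume doubling time (VDT), and become
symptomatic at an individually sampled self-detection diameter drawn from a
gamma distribution truncated at 40 mm.  Stage at detection follows a
diameter-indexed ordered-logit model (a calibration target: larger tumours
are stochastically later-stage).  COPD exacerbations are a Poisson process
whose rate depends on emphysema severity, treatment and smoking cessation;
COPD mortality multiplies a calibrated base hazard by the prior-year
exacerbation hazard ratio.  Lung-cancer mortality after diagnosis follows
stage-specific Gompertz hazards.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy import stats

from .params import (ParameterSet, LungCancerParams, SUBSTAGES,
                     SUBSTAGE_TO_GROUP)

__all__ = [
    "annual_to_monthly", "monthly_to_annual", "tumor_diameter_at",
    "diameter_to_days", "sample_vdt", "sample_self_detection_diameter",
    "monthly_onset_probability", "stage_at_detection", "stage_group_probs",
    "monthly_exacerbation_rate", "copd_death_prob", "copd_hazard_ratio",
    "lc_death_prob", "gompertz_cum_hazard", "gompertz_median_survival",
]


# ---------------------------------------------------------------------------
# probability/time conversions
# ---------------------------------------------------------------------------


def annual_to_monthly(p_annual):
    """Constant-hazard conversion: p_m = 1 - (1 - p_a)^(1/12)."""
    p = np.asarray(p_annual, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("annual probability outside [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(np.log1p(-p) / 12.0)
    return float(out) if np.isscalar(p_annual) else out


def monthly_to_annual(p_monthly):
    p = np.asarray(p_monthly, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("monthly probability outside [0, 1]")
    with np.errstate(divide="ignore"):
        out = -np.expm1(12.0 * np.log1p(-p))
    return float(out) if np.isscalar(p_monthly) else out


# ---------------------------------------------------------------------------
# tumour growth
# ---------------------------------------------------------------------------


def tumor_diameter_at(d0, vdt_days, elapsed_days):
    """Diameter after ``elapsed_days`` of growth from ``d0``.

    Volume doubles every VDT; for a spherical tumour the diameter therefore
    doubles every 3 VDTs: d = d0 * 2^(elapsed / (3 vdt)).
    """
    d0 = np.asarray(d0, dtype=float)
    vdt = np.asarray(vdt_days, dtype=float)
    t = np.asarray(elapsed_days, dtype=float)
    if np.any(vdt <= 0):
        raise ValueError("volume doubling time must be positive")
    if np.any(d0 <= 0) or np.any(t < 0):
        raise ValueError("need d0 > 0 and elapsed >= 0")
    out = d0 * np.exp2(t / (3.0 * vdt))
    return float(out) if out.ndim == 0 else out


def diameter_to_days(d0, vdt_days, target_diameter):
    """Days needed to grow from ``d0`` to ``target_diameter`` (growth-law inverse)."""
    return 3.0 * np.asarray(vdt_days, dtype=float) * np.log2(
        np.asarray(target_diameter, dtype=float) / np.asarray(d0, dtype=float))


def sample_vdt(params: ParameterSet, rng: np.random.Generator, size=None):
    """Volume doubling time (days), lognormal on the published log scale."""
    lc = params.lung_cancer
    return rng.lognormal(lc.vdt_log_mean, lc.vdt_log_sd, size=size)


def sample_self_detection_diameter(params: ParameterSet, rng: np.random.Generator,
                                   size=None, cap_mm: float | None = None):
    """Self-detection diameter (mm): gamma(shape, rate) truncated above.

    Drawn by inverse CDF so the truncation is exact; ``cap_mm=np.inf`` recovers
    the untruncated gamma (mean = shape/rate).
    """
    lc = params.lung_cancer
    cap = lc.self_detect_cap_mm if cap_mm is None else cap_mm
    scale = 1.0 / lc.self_detect_rate
    u = rng.random(size)
    fcap = stats.gamma.cdf(cap, lc.self_detect_shape, scale=scale)
    return stats.gamma.ppf(u * fcap, lc.self_detect_shape, scale=scale)


def monthly_onset_probability(lc_risk_6y):
    """Per-cycle lung-cancer onset probability from the 6-year risk."""
    r = np.asarray(lc_risk_6y, dtype=float)
    out = -np.expm1(np.log1p(-r) / 72.0)
    return float(out) if np.isscalar(lc_risk_6y) else out


# ---------------------------------------------------------------------------
# stage at detection
# ---------------------------------------------------------------------------


def stage_group_probs(diameter_mm, lc: LungCancerParams) -> np.ndarray:
    """P(stage group I..IV | diameter): ordered logit, shape (..., 4)."""
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    eta = lc.stage_slope * np.log(d)
    cum = expit(np.asarray(lc.stage_cutpoints)[..., :] - eta[..., None])  # (..., 3)
    cum = np.concatenate([cum, np.ones_like(cum[..., :1])], axis=-1)
    probs = np.diff(cum, axis=-1, prepend=0.0)
    return np.clip(probs, 0.0, 1.0)


def stage_at_detection(diameter_mm, lc: LungCancerParams, u) -> np.ndarray:
    """Substage index into SUBSTAGES, drawn from the diameter-indexed model.

    ``u`` is the uniform variate (scalar or array matching ``diameter_mm``);
    within-group substage splits reuse the conditional remainder of ``u`` so a
    single variate decides the full substage.
    """
    scalar = np.isscalar(diameter_mm) or np.ndim(diameter_mm) == 0
    d = np.atleast_1d(np.asarray(diameter_mm, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    probs = stage_group_probs(d, lc)
    cum = np.cumsum(probs, axis=-1)
    group = np.sum(u[..., None] > cum[..., :3], axis=-1).astype(np.int8)
    lower = np.take_along_axis(
        np.concatenate([np.zeros_like(cum[..., :1]), cum[..., :3]], axis=-1),
        group[..., None].astype(int), axis=-1)[..., 0]
    width = np.take_along_axis(probs, group[..., None].astype(int), axis=-1)[..., 0]
    v = np.where(width > 0, (u - lower) / np.maximum(width, 1e-300), 0.5)

    sub = np.empty(d.shape, dtype=np.int8)
    g0 = group == 0
    sub[g0] = np.where(d[g0] < lc.stage_ia_max_diameter_mm,
                       SUBSTAGES.index("IA"), SUBSTAGES.index("IB"))
    g1 = group == 1
    sub[g1] = np.where(v[g1] < lc.stage_iia_fraction,
                       SUBSTAGES.index("IIA"), SUBSTAGES.index("IIB"))
    g2 = group == 2
    sub[g2] = np.where(v[g2] < lc.stage_iiia_fraction,
                       SUBSTAGES.index("IIIA"), SUBSTAGES.index("IIIB"))
    sub[group == 3] = SUBSTAGES.index("IV")
    return np.int8(sub[0]) if scalar else sub


def substage_to_group(substage_idx) -> np.ndarray:
    table = np.asarray([SUBSTAGE_TO_GROUP[s] for s in SUBSTAGES], dtype=np.int8)
    return table[np.asarray(substage_idx, dtype=int)]


# ---------------------------------------------------------------------------
# COPD
# ---------------------------------------------------------------------------


def monthly_exacerbation_rate(severity, treated, quit_smoking, params: ParameterSet):
    """Expected exacerbations per cycle: annual rate/12 x treatment/quit RRs."""
    rates = np.asarray(params.copd.annual_exacerbation_rate, dtype=float)
    sev = np.asarray(severity, dtype=int)
    mu = rates[sev] / 12.0
    mu = mu * np.where(np.asarray(treated, dtype=bool),
                       params.copd.rr_exacerbation_treated, 1.0)
    mu = mu * np.where(np.asarray(quit_smoking, dtype=bool),
                       params.copd.rr_exacerbation_quit, 1.0)
    if np.any(mu < 0):
        raise ValueError("negative exacerbation rate")
    return mu


def copd_hazard_ratio(exacerbations_last_12mo, params: ParameterSet):
    """HR for COPD death by prior-year exacerbation count: 1 / HR(1-2) / HR(3+)."""
    k = np.asarray(exacerbations_last_12mo, dtype=int)
    return np.where(k >= 3, params.copd.hr_mortality_3plus,
                    np.where(k >= 1, params.copd.hr_mortality_1_2, 1.0))


def copd_death_prob(exacerbations_last_12mo, params: ParameterSet,
                    base_monthly_hazard: float | None = None):
    """Per-cycle COPD death probability 1 - exp(-h0 * HR)."""
    h0 = params.copd.base_monthly_hazard if base_monthly_hazard is None \
        else base_monthly_hazard
    hr = copd_hazard_ratio(exacerbations_last_12mo, params)
    return -np.expm1(-h0 * hr)


# ---------------------------------------------------------------------------
# lung-cancer survival after diagnosis
# ---------------------------------------------------------------------------


def gompertz_cum_hazard(c: float, b: float, t0, t1):
    """Integral of b*exp(c*t) over [t0, t1] (months)."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if b < 0:
        raise ValueError("Gompertz rate b must be >= 0")
    if c == 0.0:
        return b * (t1 - t0)
    return b * (np.exp(c * t1) - np.exp(c * t0)) / c


def lc_death_prob(substage_idx, months_since_dx, params: ParameterSet):
    """Per-cycle lung-cancer death probability for a diagnosed tumour."""
    sub = np.asarray(substage_idx, dtype=int)
    if np.any(sub < 0):
        raise ValueError("lc_death_prob requires a diagnosed (staged) tumour")
    m = np.asarray(months_since_dx, dtype=float)
    cs = np.asarray([params.lung_cancer.gompertz_c[s] for s in SUBSTAGES])
    bs = np.asarray([params.lung_cancer.gompertz_b[s] for s in SUBSTAGES])
    c, b = cs[sub], bs[sub]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(c == 0.0, b,
                     b * (np.exp(c * (m + 1)) - np.exp(c * m)) / np.where(c == 0, 1.0, c))
    return -np.expm1(-h)


def gompertz_median_survival(c: float, b: float) -> float:
    """Closed-form median of the Gompertz survival time, inf if never reached."""
    if b <= 0:
        return np.inf
    if c == 0.0:
        return np.log(2.0) / b
    arg = 1.0 + c * np.log(2.0) / b
    if arg <= 0:  # c < 0 and cure fraction above one half
        return np.inf
    return float(np.log(arg) / c)
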