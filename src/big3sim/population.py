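"""Synthetic NLST-eligible cohort generation.

The original analysis samples 10,000 individuals from restricted NLST
individual-level data.  This module emulates that population from configurable
marginal distributions: current/former heavy smokers aged 55-74, >30
pack-years, former smokers having quit <15 years ago, with sex, family history
of lung cancer, prior CVD/COPD diagnoses, a Fleischner emphysema severity with
an exacerbation group, a coronary-artery-calcium (CAC) category, and
individually assigned annual CHD/stroke risks and a 6-year lung-cancer risk.

Attributes are drawn from independent marginals except an optional Gaussian
copula correlation between age and pack-years.  No attempt is made to
reproduce the true NLST joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .params import ParameterSet, ParameterError, EMPHYSEMA_LEVELS, CAC_LEVELS

COHORT_COLUMNS = [
    "id", "age", "sex", "smoking_status", "pack_years", "quit_years",
    "family_history_lc", "prior_cvd", "prior_copd_dx",
    "emphysema_severity", "exacerbation_group", "cac_category",
    "chd_risk_annual", "chd_risk_annual_former",
    "stroke_risk_annual", "stroke_risk_annual_former",
    "lc_risk_6y", "lc_risk_6y_former", "baseline_utility",
]

# default entry-age weights, 5-year bands 55-59/60-64/65-69/70-74, front-loaded
# the way LC-screening-eligible trial populations are
_AGE_BAND_WEIGHTS = (0.43, 0.31, 0.18, 0.08)


@dataclass
class CohortConfig:
    """Marginal distributions for the synthetic screening population."""

    n_individuals: int = 10_000
    seed: int = 0
    sex_male_fraction: float = 0.59
    smoking_current_fraction: float = 0.4867
    family_history_lc_fraction: float = 0.22
    prior_cvd_fraction: float = 0.15
    prior_copd_dx_fraction: float = 0.05
    age_band_weights: tuple[float, ...] = _AGE_BAND_WEIGHTS
    # pack-years = 30 + gamma(shape, scale); defaults give mean ~56, median ~48
    pack_years_gamma_shape: float = 2.2
    pack_years_gamma_scale: float = 11.8
    age_packyears_correlation: float = 0.2  # Gaussian copula
    quit_years_max: float = 15.0
    cac_probs: tuple[float, ...] = (0.25, 0.25, 0.30, 0.20)  # none..severe
    # optional per-sex emphysema severity override (e.g. an age-specific
    # table for this 55-74 cohort); None uses the published sex aggregates
    emphysema_prevalence_override: dict | None = None

    def validate(self) -> list[str]:
        errs = []
        if self.n_individuals <= 0:
            errs.append("n_individuals must be > 0")
        for nm in ("sex_male_fraction", "smoking_current_fraction",
                   "family_history_lc_fraction", "prior_cvd_fraction",
                   "prior_copd_dx_fraction"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{nm}: fraction {v!r} outside [0, 1]")
        if len(self.age_band_weights) != 4 or abs(sum(self.age_band_weights) - 1) > 1e-9:
            errs.append("age_band_weights must be 4 weights summing to 1")
        if len(self.cac_probs) != 4 or abs(sum(self.cac_probs) - 1) > 1e-9:
            errs.append("cac_probs must be 4 probabilities summing to 1")
        if not -1.0 < self.age_packyears_correlation < 1.0:
            errs.append("age_packyears_correlation must be in (-1, 1)")
        if not 0 < self.quit_years_max <= 15:
            errs.append("quit_years_max must be in (0, 15]")
        return errs

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# coefficient files
# ---------------------------------------------------------------------------


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("big3sim.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_chd_coeffs() -> dict:
    """Packaged synthetic CHD-risk equation coefficients."""
    return _load_packaged_yaml("chd_risk_synthetic.yaml")


def load_stroke_coeffs() -> dict:
    """Packaged synthetic stroke-risk equation coefficients (no CAC terms)."""
    return _load_packaged_yaml("stroke_risk_synthetic.yaml")


def load_attendance_coeffs() -> dict:
    """Packaged synthetic per-strategy attendance coefficients."""
    return _load_packaged_yaml("attendance_synthetic.yaml")


# ---------------------------------------------------------------------------
# risk equations
# ---------------------------------------------------------------------------

_RISK_CLIP = (1e-9, 1.0 - 1e-9)


def assign_chd_risk(age, male, current_smoker, pack_years, cac_category, coeffs) -> np.ndarray:
    """Annual CHD event probability from the logistic risk equation.

    ``cac_category`` is an integer code 0..3 (none..severe).  Monotone
    non-decreasing in age and CAC category for non-negative coefficients.
    Accepts scalars or arrays.
    """
    for key in ("intercept", "age_per_year", "male", "current_smoker",
                "pack_years_per10", "cac"):
        if key not in coeffs:
            raise ParameterError(f"CHD risk coefficients missing '{key}'")
    cac_terms = np.asarray([coeffs["cac"][lvl] for lvl in CAC_LEVELS], dtype=float)
    lp = (coeffs["intercept"]
          + coeffs["age_per_year"] * (np.asarray(age, dtype=float) - 61.0)
          + coeffs["male"] * np.asarray(male, dtype=float)
          + coeffs["current_smoker"] * np.asarray(current_smoker, dtype=float)
          + coeffs["pack_years_per10"] * (np.asarray(pack_years, dtype=float) - 48.0) / 10.0
          + cac_terms[np.asarray(cac_category, dtype=int)])
    return np.clip(expit(lp), *_RISK_CLIP)


def assign_stroke_risk(age, male, current_smoker, pack_years, coeffs) -> np.ndarray:
    """Annual stroke probability; coronary calcium does not enter."""
    for key in ("intercept", "age_per_year", "male", "current_smoker",
                "pack_years_per10"):
        if key not in coeffs:
            raise ParameterError(f"stroke risk coefficients missing '{key}'")
    if "cac" in coeffs:
        raise ParameterError("stroke risk equation must not include calcium-score terms")
    lp = (coeffs["intercept"]
          + coeffs["age_per_year"] * (np.asarray(age, dtype=float) - 61.0)
          + coeffs["male"] * np.asarray(male, dtype=float)
          + coeffs["current_smoker"] * np.asarray(current_smoker, dtype=float)
          + coeffs["pack_years_per10"] * (np.asarray(pack_years, dtype=float) - 48.0) / 10.0)
    return np.clip(expit(lp), *_RISK_CLIP)


def assign_lc_risk(current_smoker, params: ParameterSet, rng: np.random.Generator) -> np.ndarray:
    """6-year lung-cancer risk per individual.

    Sampled from a beta distribution matched to the status-specific mean and
    SD, truncated to the published range.  Acts as the simplified per-status
    risk; a full covariate-based risk model can be plugged in by overwriting
    the ``lc_risk_6y`` cohort column.
    """
    lc = params.lung_cancer
    cur = np.asarray(current_smoker, dtype=bool)
    mean = np.where(cur, lc.risk6y_mean_current, lc.risk6y_mean_former)
    sd = lc.risk6y_sd
    var = np.minimum(sd * sd, 0.95 * mean * (1 - mean))
    k = mean * (1 - mean) / var - 1.0
    draws = rng.beta(mean * k, (1 - mean) * k)
    return np.clip(draws, lc.risk6y_lo, lc.risk6y_hi)


def assign_emphysema(male, prevalence_table, rng: np.random.Generator) -> np.ndarray:
    """Fleischner severity code 0..4 from the sex-specific categorical table.

    ``prevalence_table`` maps {'male': probs, 'female': probs} over the five
    severity levels; each row must sum to 1 (±1e-9).
    """
    male = np.asarray(male, dtype=bool)
    out = np.zeros(male.shape, dtype=np.int8)
    for key, mask in (("male", male), ("female", ~male)):
        probs = np.asarray(prevalence_table[key], dtype=float)
        if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"emphysema prevalence for {key} must be 5 probabilities summing to 1")
        n = int(mask.sum())
        if n:
            out[mask] = rng.choice(5, size=n, p=probs)
    return out


def baseline_utility_for_age(age, utilities) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    return np.where(age <= 60, utilities.baseline_le60,
                    np.where(age <= 70, utilities.baseline_60_70,
                             utilities.baseline_gt70))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig, params: ParameterSet,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate a synthetic NLST-eligible cohort as a DataFrame.

    Deterministic given (config, params, seed); ``seed=None`` uses
    ``config.seed``.  Every row satisfies the eligibility filter (age 55-74,
    pack-years > 30, former smokers quit < 15 y ago).
    """
    errs = config.validate()
    if errs:
        raise ParameterError("invalid cohort config:\n  " + "\n  ".join(errs))
    params.require_valid()
    n = config.n_individuals
    rng = np.random.default_rng(config.seed if seed is None else seed)

    male = rng.random(n) < config.sex_male_fraction
    current = rng.random(n) < config.smoking_current_fraction

    # age and pack-years through a Gaussian copula
    rho = config.age_packyears_correlation
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    u_age, u_py = _norm_cdf(z[:, 0]), _norm_cdf(z[:, 1])
    band_edges = np.cumsum(config.age_band_weights)
    band = np.searchsorted(band_edges, u_age, side="right").clip(0, 3)
    # uniform integer age inside the 5-year band
    u_within = (u_age - np.concatenate(([0], band_edges))[band]) / np.asarray(
        config.age_band_weights)[band]
    age = 55 + 5 * band + np.floor(np.clip(u_within, 0, 1 - 1e-12) * 5).astype(int)
    from scipy.stats import gamma as _gamma_dist
    pack_years = 30.0 + _gamma_dist.ppf(
        np.clip(u_py, 1e-12, 1 - 1e-12),
        config.pack_years_gamma_shape, scale=config.pack_years_gamma_scale)

    quit_years = np.where(current, 0.0, rng.uniform(0.0, config.quit_years_max, n))
    fam = rng.random(n) < config.family_history_lc_fraction
    prior_cvd = rng.random(n) < config.prior_cvd_fraction
    prior_copd = rng.random(n) < config.prior_copd_dx_fraction

    prev_table = config.emphysema_prevalence_override or {
        "male": params.copd.prevalence_male,
        "female": params.copd.prevalence_female}
    emph = assign_emphysema(male, prev_table, rng)
    exac_group = emph.astype(int)  # expected exacerbations/y tier follows severity
    cac = rng.choice(4, size=n, p=np.asarray(config.cac_probs))

    chd_coeffs = params.chd_coeffs or load_chd_coeffs()
    stroke_coeffs = params.stroke_coeffs or load_stroke_coeffs()
    chd_now = assign_chd_risk(age, male, current, pack_years, cac, chd_coeffs)
    chd_former = assign_chd_risk(age, male, False, pack_years, cac, chd_coeffs)
    stroke_now = assign_stroke_risk(age, male, current, pack_years, stroke_coeffs)
    stroke_former = assign_stroke_risk(age, male, False, pack_years, stroke_coeffs)

    lc_risk = assign_lc_risk(current, params, rng)
    # risk if a current smoker quits during follow-up: scaled by the ratio of
    # status-level means (documented simplification)
    ratio = params.lung_cancer.risk6y_mean_former / params.lung_cancer.risk6y_mean_current
    lc_risk_former = np.where(current, np.clip(lc_risk * ratio,
                                               params.lung_cancer.risk6y_lo,
                                               params.lung_cancer.risk6y_hi), lc_risk)

    df = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "age": age.astype(np.int16),
        "sex": np.where(male, "male", "female"),
        "smoking_status": np.where(current, "current", "former"),
        "pack_years": pack_years,
        "quit_years": quit_years,
        "family_history_lc": fam,
        "prior_cvd": prior_cvd,
        "prior_copd_dx": prior_copd,
        "emphysema_severity": np.asarray(EMPHYSEMA_LEVELS)[emph],
        "exacerbation_group": exac_group,
        "cac_category": np.asarray(CAC_LEVELS)[cac],
        "chd_risk_annual": chd_now,
        "chd_risk_annual_former": chd_former,
        "stroke_risk_annual": stroke_now,
        "stroke_risk_annual_former": stroke_former,
        "lc_risk_6y": lc_risk,
        "lc_risk_6y_former": lc_risk_former,
        "baseline_utility": baseline_utility_for_age(age, params.utilities),
    })
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """NLST-eligibility and internal-consistency check; empty list when clean."""
    errs = []
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            errs.append(f"missing column {col}")
    if errs:
        return errs
    if ((df["age"] < 55) | (df["age"] > 74)).any():
        errs.append("age outside [55, 74]")
    if (df["pack_years"] <= 30).any():
        errs.append("pack_years not > 30")
    former = df["smoking_status"] == "former"
    if (df.loc[former, "quit_years"] >= 15).any():
        errs.append("former smoker quit >= 15 years ago")
    if (df.loc[~former, "quit_years"] != 0).any():
        errs.append("current smoker with nonzero quit_years")
    for col in ("chd_risk_annual", "stroke_risk_annual", "lc_risk_6y", "baseline_utility"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            errs.append(f"{col} outside [0, 1]")
    none_emph = df["emphysema_severity"] == "none"
    if (df.loc[none_emph, "exacerbation_group"] != 0).any():
        errs.append("exacerbation_group nonzero with no emphysema")
    return errs


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errs = validate_cohort(df)
    if errs:
        raise ParameterError(f"{path}: invalid cohort:\n  " + "\n  ".join(errs))
    return df


def _norm_cdf(x: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr
    return ndtr(x)
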