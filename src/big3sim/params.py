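"""Model parameters: point estimates, uncertainty distributions, validation.

Every quantity the simulator consumes lives in a :class:`ParameterSet` — screening
test characteristics, natural-history inputs (tumour growth, exacerbation rates,
stage-specific Gompertz survival), treatment effects, 2022-€ costs, utility
weights and discount rates.  Each uncertain quantity carries a probabilistic
sensitivity analysis (PSA) distribution; :meth:`ParameterSet.sample_psa` returns a
fresh, independently sampled set respecting the printed constraints (cessation
proportion with screening >= without; COPD mortality hazard ratio for 3+
exacerbations >= that for 1-2; event-type shares on the simplex).

Values are stored in plain dataclasses and round-trip through YAML so a study
can be re-run from an edited parameter file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

# Stage codes used across the package: 7 TNM substages collapsed to 4 groups
# for stage-model calibration, utilities and treatment costs.
SUBSTAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")
STAGE_GROUPS = ("I", "II", "III", "IV")
SUBSTAGE_TO_GROUP = {"IA": 0, "IB": 0, "IIA": 1, "IIB": 1, "IIIA": 2, "IIIB": 2, "IV": 3}
EMPHYSEMA_LEVELS = ("none", "mild", "moderate", "severe", "very_severe")
CAC_LEVELS = ("none", "mild", "moderate", "severe")
CHD_EVENT_TYPES = ("mi", "angina", "chd_death", "cardiac_arrest")

DAYS_PER_MONTH = 365.25 / 12.0


class ParameterError(ValueError):
    """A parameter file or override failed validation."""


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------


@dataclass
class ScreeningParams:
    """LDCT test performance and screening logistics."""

    attendance_mean: float = 0.75
    attendance_lo: float = 0.63
    attendance_hi: float = 0.974
    attendance_psa_sd: float = 0.25  # on the [lo, hi]-rescaled beta scale
    specificity: float = 0.992
    specificity_sd: float = 0.00076
    # piecewise-linear sensitivity in tumour diameter d (mm):
    # 0 below sens_d_lo, slope*d + intercept on [d_lo, d_hi), 1 at >= d_hi
    sens_d_lo: float = 3.0
    sens_d_hi: float = 5.0
    sens_slope: float = 0.5
    sens_intercept: float = -1.5
    interval_months: int = 12
    start_age: int = 55
    stop_age: int = 74
    # referral proportions after a moderate/severe coronary-calcium finding
    statin_prop: float = 0.35
    ace_prop_no_history: float = 0.22
    ace_prop_history: float = 0.0
    # background preventative treatment among individuals with prior CVD
    background_statin_history: float = 0.50
    background_ace_history: float = 0.90


@dataclass
class LungCancerParams:
    """Lung-tumour natural history and survival after diagnosis."""

    risk6y_mean_current: float = 0.10068
    risk6y_mean_former: float = 0.06526
    risk6y_sd: float = 0.05        # between-individual spread
    risk6y_mean_psa_sd: float = 0.01  # uncertainty of the status-level mean
    risk6y_lo: float = 0.006
    risk6y_hi: float = 0.323
    # lifetime cumulative LC incidence among heavy smokers: the published
    # aggregate the onset process is calibrated to.  The 6-y PLCO-style risk
    # extrapolated as a flat lifetime hazard overshoots it, so the engine
    # multiplies the onset hazard by the calibrated scale below.
    cumulative_incidence_lifetime: float = 0.22
    onset_hazard_scale: float = 0.570  # calibrated to the lifetime incidence
    vdt_log_mean: float = 4.59  # log(days); geometric mean ~98.5 d
    vdt_log_sd: float = 0.2198
    self_detect_shape: float = 3.74
    self_detect_rate: float = 0.08  # per mm
    self_detect_cap_mm: float = 40.0
    start_diameter_mm: float = 0.33
    # Gompertz hazard h(t) = b * exp(c * t), t in months since diagnosis
    gompertz_c: dict[str, float] = field(
        default_factory=lambda: {
            "IA": -0.025, "IB": -0.020, "IIA": -0.028, "IIB": -0.046,
            "IIIA": -0.033, "IIIB": -0.038, "IV": -0.075,
        }
    )
    gompertz_b: dict[str, float] = field(
        default_factory=lambda: {
            "IA": 0.007, "IB": 0.007, "IIA": 0.015, "IIB": 0.016,
            "IIIA": 0.034, "IIIB": 0.051, "IV": 0.143,
        }
    )
    # diameter-indexed ordered-logit stage-at-detection model (calibrated):
    # P(group <= k | d) = expit(cutpoint_k - slope * ln d)
    stage_slope: float = 1.550
    stage_cutpoints: tuple[float, float, float] = (4.547, 4.942, 5.785)
    # substage splits inside a stage group
    stage_ia_max_diameter_mm: float = 30.0  # I -> IA below, IB at/above
    stage_iia_fraction: float = 0.5
    stage_iiia_fraction: float = 0.6
    operable_substages: tuple[str, ...] = ("IA", "IB", "IIA", "IIB", "IIIA")


@dataclass
class CopdParams:
    """Emphysema prevalence, exacerbation process and COPD mortality."""

    # Fleischner severity prevalence per sex (none..very_severe)
    prevalence_male: tuple[float, ...] = (0.34, 0.41, 0.22, 0.01, 0.02)
    prevalence_female: tuple[float, ...] = (0.40, 0.51, 0.07, 0.01, 0.01)
    annual_exacerbation_rate: tuple[float, ...] = (0.0, 0.754, 0.865, 1.095, 1.35)
    exacerbation_rate_psa_cv: float = 0.2
    rr_exacerbation_treated: float = 0.82
    rr_exacerbation_treated_sd: float = 0.0475
    rr_exacerbation_quit: float = 0.78
    rr_exacerbation_quit_sd: float = 0.03
    severe_exacerbation_fraction: float = 0.079  # share of exacerbations that are severe
    hr_mortality_1_2: float = 2.00
    hr_mortality_1_2_ci: tuple[float, float] = (1.01, 3.98)
    hr_mortality_3plus: float = 4.13
    hr_mortality_3plus_ci: tuple[float, float] = (1.8, 9.45)
    base_monthly_hazard: float = 1.04e-4  # calibrated to ~130 COPD deaths /10k in 10 y
    dx_prob_per_exacerbation: float = 0.0135


@dataclass
class CvdParams:
    """CHD/stroke event process and preventative-treatment effects."""

    chd_type_probs: tuple[float, ...] = (0.45, 0.35, 0.16, 0.04)  # mi/angina/chd_death/arrest
    chd_type_dirichlet_conc: float = 100.0  # total concentration; 0 = fixed
    rr_statin_chd: float = 0.62
    rr_statin_chd_sd: float = 0.05
    rr_statin_stroke: float = 0.83
    rr_statin_stroke_sd: float = 0.04
    rr_ace_chd: float = 0.79
    rr_ace_chd_sd: float = 0.04
    rr_ace_stroke: float = 0.86
    rr_ace_stroke_sd: float = 0.05
    cardiac_arrest_fatality: float = 0.0
    stroke_fatality: float = 0.15


@dataclass
class MortalityParams:
    """Other-cause mortality: age-graded exponential (Gompertz-like) hazard.

    ``other_cause_annual`` is the annual probability at the reference age;
    the hazard doubles roughly every 8 years (log-slope 0.085/y), matching
    the age gradient of general-population all-cause mortality.  A log-slope
    of 0 recovers a flat annual probability.
    """

    other_cause_annual: float = 0.01
    other_cause_annual_sd: float = 0.005
    other_cause_ref_age: float = 72.0
    other_cause_log_slope: float = 0.085


@dataclass
class CessationParams:
    """Smoking-cessation proportions; applied once per individual."""

    p_base: float = 0.11   # base-case point value without screening participation
    p_screen: float = 0.21  # base-case point value for screening participants
    # PSA uniform ranges (with-screening draw constrained >= without)
    psa_base_lo: float = 0.0
    psa_base_hi: float = 0.6
    psa_screen_lo: float = 0.1
    psa_screen_hi: float = 0.6


@dataclass
class CostTable:
    """2022-€ cost inputs. SDs absent in the source default to 20% of the mean."""

    default_psa_cv: float = 0.2  # for costs with no quoted dispersion
    invitation: float = 6.0
    ldct_scan: float = 176.0
    diagnosis: float = 1747.0  # PET scan and biopsy work-up
    lc_surgery_onceoff: float = 15840.0
    lc_monthly_stage_i_ii: float = 60.0
    lc_monthly_stage_i_ii_sd: float = 13.0
    lc_monthly_stage_iii: float = 710.0
    lc_monthly_stage_iii_sd: float = 18.0
    lc_monthly_stage_iv: float = 899.0
    lc_monthly_stage_iv_sd: float = 106.0
    lc_treatment_months_i_iii: float = 20.9
    lc_treatment_months_i_iii_sd: float = 26.0
    lc_treatment_months_iv: float = 12.6
    lc_treatment_months_iv_sd: float = 11.0
    copd_annual: tuple[float, ...] = (288.0, 358.0, 339.0, 593.0)  # mild..very severe
    copd_annual_sd: tuple[float, ...] = (293.0, 364.0, 406.0, 602.0)
    exacerbation: float = 525.0
    exacerbation_sd: float = 8049.0
    statin_annual: float = 40.0
    ace_annual: float = 305.0
    mi: float = 6348.0
    mi_sd: float = 8732.0
    cardiac_arrest_or_angina: float = 33575.0
    cardiac_arrest_or_angina_sd: float = 19612.0
    stroke_monthly_1_6: float = 2936.0
    stroke_monthly_1_6_sd: float = 1532.0
    stroke_monthly_7_13: float = 780.0
    stroke_monthly_7_13_sd: float = 975.0


@dataclass
class UtilityTable:
    """Baseline utilities by age band and multiplicative condition disutilities."""

    baseline_le60: float = 0.857
    baseline_le60_sd: float = 0.183
    baseline_60_70: float = 0.839
    baseline_60_70_sd: float = 0.179
    baseline_gt70: float = 0.852
    baseline_gt70_sd: float = 0.148
    copd_gold: tuple[float, ...] = (0.90, 0.76, 0.75, 0.55)  # GOLD 1..4
    copd_gold_sd: tuple[float, ...] = (0.11, 0.27, 0.30, 0.31)
    exacerbation_moderate: float = 0.98
    exacerbation_severe: float = 0.95
    lc_stage: tuple[float, ...] = (0.71, 0.68, 0.67, 0.66)  # group I..IV
    lc_stage_sd: tuple[float, ...] = (0.005, 0.010, 0.005, 0.005)
    stroke_first_month: float = 0.64
    stroke_first_month_sd: float = 0.02
    stroke_after: float = 0.80
    stroke_after_sd: float = 0.01
    chd_first_month: float = 0.883
    chd_first_month_sd: float = 0.01
    chd_after: float = 0.884
    chd_after_sd: float = 0.01


@dataclass
class SimulationParams:
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    warmup_months: int = 120
    max_age: int = 100
    copd_death_applies_from_severity: int = 1  # mild and above


@dataclass
class ParameterSet:
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    lung_cancer: LungCancerParams = field(default_factory=LungCancerParams)
    copd: CopdParams = field(default_factory=CopdParams)
    cvd: CvdParams = field(default_factory=CvdParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    cessation: CessationParams = field(default_factory=CessationParams)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    sim: SimulationParams = field(default_factory=SimulationParams)
    # risk-equation and attendance coefficient sets (populated by loaders;
    # None means "use the packaged synthetic defaults")
    chd_coeffs: dict[str, Any] | None = None
    stroke_coeffs: dict[str, Any] | None = None
    attendance_coeffs: dict[str, Any] | None = None

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of human-readable violations; empty when valid."""
        errs: list[str] = []

        def prob(name: str, v: float) -> None:
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name}: probability {v!r} outside [0, 1]")

        def pos(name: str, v: float, strict: bool = False) -> None:
            if v < 0 or (strict and v == 0):
                errs.append(f"{name}: {v!r} must be {'>' if strict else '>='} 0")

        s = self.screening
        for nm in ("attendance_mean", "attendance_lo", "attendance_hi", "specificity",
                   "statin_prop", "ace_prop_no_history", "ace_prop_history",
                   "background_statin_history", "background_ace_history"):
            prob(f"screening.{nm}", getattr(s, nm))
        if s.sens_d_lo >= s.sens_d_hi:
            errs.append("screening.sens_d_lo must be below sens_d_hi")
        if s.interval_months <= 0:
            errs.append("screening.interval_months must be positive")

        lc = self.lung_cancer
        for nm in ("risk6y_mean_current", "risk6y_mean_former", "risk6y_lo", "risk6y_hi"):
            prob(f"lung_cancer.{nm}", getattr(lc, nm))
        pos("lung_cancer.vdt_log_sd", lc.vdt_log_sd)
        pos("lung_cancer.self_detect_shape", lc.self_detect_shape, strict=True)
        pos("lung_cancer.self_detect_rate", lc.self_detect_rate, strict=True)
        pos("lung_cancer.self_detect_cap_mm", lc.self_detect_cap_mm, strict=True)
        pos("lung_cancer.start_diameter_mm", lc.start_diameter_mm, strict=True)
        if lc.start_diameter_mm > 3.0:
            errs.append("lung_cancer.start_diameter_mm must be <= 3 mm "
                        "(smallest screen-detectable size)")
        for st in SUBSTAGES:
            if st not in lc.gompertz_b or st not in lc.gompertz_c:
                errs.append(f"lung_cancer.gompertz missing stage {st}")
            elif lc.gompertz_b[st] < 0:
                errs.append(f"lung_cancer.gompertz_b[{st}] must be >= 0")
        if not np.all(np.diff(lc.stage_cutpoints) > 0):
            errs.append("lung_cancer.stage_cutpoints must be strictly increasing")

        cp = self.copd
        for sex, tab in (("male", cp.prevalence_male), ("female", cp.prevalence_female)):
            if len(tab) != 5:
                errs.append(f"copd.prevalence_{sex}: expected 5 severity levels")
            elif abs(sum(tab) - 1.0) > 1e-9:
                errs.append(f"copd.prevalence_{sex}: probabilities sum to {sum(tab):.6f}, not 1")
        if cp.annual_exacerbation_rate[0] != 0.0:
            errs.append("copd.annual_exacerbation_rate: rate for 'none' must be 0")
        if any(r < 0 for r in cp.annual_exacerbation_rate):
            errs.append("copd.annual_exacerbation_rate: rates must be >= 0")
        if cp.hr_mortality_1_2 < 1 or cp.hr_mortality_3plus < cp.hr_mortality_1_2:
            errs.append("copd mortality hazard ratios must satisfy 1 <= HR(1-2) <= HR(3+)")
        prob("copd.dx_prob_per_exacerbation", cp.dx_prob_per_exacerbation)
        prob("copd.severe_exacerbation_fraction", cp.severe_exacerbation_fraction)
        pos("copd.base_monthly_hazard", cp.base_monthly_hazard)

        cv = self.cvd
        if abs(sum(cv.chd_type_probs) - 1.0) > 1e-9:
            errs.append("cvd.chd_type_probs must sum to 1")
        for nm in ("rr_statin_chd", "rr_statin_stroke", "rr_ace_chd", "rr_ace_stroke"):
            v = getattr(cv, nm)
            if v <= 0:
                errs.append(f"cvd.{nm}: relative risk {v!r} must be > 0")
        prob("cvd.cardiac_arrest_fatality", cv.cardiac_arrest_fatality)
        prob("cvd.stroke_fatality", cv.stroke_fatality)

        prob("mortality.other_cause_annual", self.mortality.other_cause_annual)

        ce = self.cessation
        prob("cessation.p_base", ce.p_base)
        prob("cessation.p_screen", ce.p_screen)
        if ce.p_screen < ce.p_base:
            errs.append("cessation.p_screen must be >= cessation.p_base")

        for f in dataclasses.fields(self.costs):
            v = getattr(self.costs, f.name)
            vals = v if isinstance(v, (tuple, list)) else (v,)
            for x in vals:
                if x < 0:
                    errs.append(f"costs.{f.name}: negative cost {x!r}")

        u = self.utilities
        for f in dataclasses.fields(u):
            if f.name.endswith("_sd"):
                continue
            v = getattr(u, f.name)
            vals = v if isinstance(v, (tuple, list)) else (v,)
            for x in vals:
                if not (0.0 <= x <= 1.0):
                    errs.append(f"utilities.{f.name}: weight {x!r} outside [0, 1]")

        sm = self.sim
        for nm in ("discount_rate_costs", "discount_rate_effects"):
            if getattr(sm, nm) < 0:
                errs.append(f"sim.{nm} must be >= 0")
        if sm.warmup_months < 0:
            errs.append("sim.warmup_months must be >= 0")
        return errs

    def require_valid(self) -> "ParameterSet":
        errs = self.validate()
        if errs:
            raise ParameterError("invalid parameters:\n  " + "\n  ".join(errs))
        return self

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTION_TYPES:
                sect = _SECTION_TYPES[f.name]
                known = {x.name for x in dataclasses.fields(sect)}
                unknown = set(v) - known
                if unknown:
                    raise ParameterError(
                        f"unknown field(s) in section '{f.name}': {sorted(unknown)}")
                sv = {k: _coerce(sect, k, x) for k, x in v.items()}
                kwargs[f.name] = sect(**sv)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())

    # -- probabilistic sensitivity analysis --------------------------------

    def sample_psa(self, rng: np.random.Generator) -> "ParameterSet":
        """Draw one PSA realisation of the parameter set.

        Probabilities and utilities are beta (moment-matched), relative risks
        beta, costs gamma, treatment durations truncated normal, COPD hazard
        ratios truncated normal inside the printed 95% CI with HR(3+) forced
        above HR(1-2), CHD event types Dirichlet, and cessation proportions
        the printed uniforms with the with-screening draw at least the
        without-screening draw.

        Mean-parameter uncertainty for mean±SD rows is the quoted SD capped
        at a 20% coefficient of variation: several quoted dispersions are
        patient-level SDs (e.g., cost per exacerbation 525 ± 8049, treatment
        duration 20.9 ± 26 months) which, taken as the uncertainty of the
        *mean*, yield degenerate draws (gamma shape 0.004; negative
        durations).  The 20% ceiling is the source's own fallback convention
        for costs without dispersion data.  Interval-based inputs (hazard-
        ratio CIs, attendance range, cessation uniforms) are sampled from
        the printed intervals unchanged.
        """
        p = self.copy()

        s = p.screening
        s.specificity = _beta(rng, self.screening.specificity, self.screening.specificity_sd)
        # attendance level: beta rescaled onto the printed attainable range
        lo, hi = self.screening.attendance_lo, self.screening.attendance_hi
        m = (self.screening.attendance_mean - lo) / (hi - lo)
        s.attendance_mean = lo + (hi - lo) * _beta(rng, m, self.screening.attendance_psa_sd)

        lc = p.lung_cancer
        lc.risk6y_mean_current = float(np.clip(
            _beta(rng, self.lung_cancer.risk6y_mean_current,
                  self.lung_cancer.risk6y_mean_psa_sd),
            self.lung_cancer.risk6y_lo, self.lung_cancer.risk6y_hi))
        lc.risk6y_mean_former = float(np.clip(
            _beta(rng, self.lung_cancer.risk6y_mean_former,
                  self.lung_cancer.risk6y_mean_psa_sd),
            self.lung_cancer.risk6y_lo, lc.risk6y_mean_current))

        cp = p.copd
        cp.rr_exacerbation_treated = _beta(
            rng, self.copd.rr_exacerbation_treated, self.copd.rr_exacerbation_treated_sd)
        cp.rr_exacerbation_quit = _beta(
            rng, self.copd.rr_exacerbation_quit, self.copd.rr_exacerbation_quit_sd)
        cp.hr_mortality_1_2 = _truncnorm(
            rng, self.copd.hr_mortality_1_2, _sd_from_ci(self.copd.hr_mortality_1_2_ci),
            *self.copd.hr_mortality_1_2_ci)
        hr3 = _truncnorm(
            rng, self.copd.hr_mortality_3plus, _sd_from_ci(self.copd.hr_mortality_3plus_ci),
            *self.copd.hr_mortality_3plus_ci)
        cp.hr_mortality_3plus = max(hr3, cp.hr_mortality_1_2)
        cp.annual_exacerbation_rate = tuple(
            0.0 if r == 0 else _gamma(rng, r, self.copd.exacerbation_rate_psa_cv * r)
            for r in self.copd.annual_exacerbation_rate)

        cv = p.cvd
        if self.cvd.chd_type_dirichlet_conc > 0:
            cv.chd_type_probs = tuple(rng.dirichlet(
                np.asarray(self.cvd.chd_type_probs)
                * self.cvd.chd_type_dirichlet_conc))
        cv.rr_statin_chd = _beta(rng, self.cvd.rr_statin_chd, self.cvd.rr_statin_chd_sd)
        cv.rr_statin_stroke = _beta(rng, self.cvd.rr_statin_stroke, self.cvd.rr_statin_stroke_sd)
        cv.rr_ace_chd = _beta(rng, self.cvd.rr_ace_chd, self.cvd.rr_ace_chd_sd)
        cv.rr_ace_stroke = _beta(rng, self.cvd.rr_ace_stroke, self.cvd.rr_ace_stroke_sd)

        p.mortality.other_cause_annual = _beta(
            rng, self.mortality.other_cause_annual, self.mortality.other_cause_annual_sd)

        ce = p.cessation
        ce.p_base = float(rng.uniform(self.cessation.psa_base_lo, self.cessation.psa_base_hi))
        ce.p_screen = float(rng.uniform(
            max(self.cessation.psa_screen_lo, ce.p_base), self.cessation.psa_screen_hi))

        c0, c = self.costs, p.costs
        c.invitation = _gamma(rng, c0.invitation, c0.default_psa_cv * c0.invitation)
        c.ldct_scan = _gamma(rng, c0.ldct_scan, c0.default_psa_cv * c0.ldct_scan)
        c.diagnosis = _gamma(rng, c0.diagnosis, c0.default_psa_cv * c0.diagnosis)
        c.lc_surgery_onceoff = _gamma(rng, c0.lc_surgery_onceoff, c0.default_psa_cv * c0.lc_surgery_onceoff)
        c.lc_monthly_stage_i_ii = _gamma(rng, c0.lc_monthly_stage_i_ii, c0.lc_monthly_stage_i_ii_sd)
        c.lc_monthly_stage_iii = _gamma(rng, c0.lc_monthly_stage_iii, c0.lc_monthly_stage_iii_sd)
        c.lc_monthly_stage_iv = _gamma(rng, c0.lc_monthly_stage_iv, c0.lc_monthly_stage_iv_sd)
        c.lc_treatment_months_i_iii = _truncnorm(
            rng, c0.lc_treatment_months_i_iii,
            _cap(c0.lc_treatment_months_i_iii, c0.lc_treatment_months_i_iii_sd),
            1.0, 120.0)
        c.lc_treatment_months_iv = _truncnorm(
            rng, c0.lc_treatment_months_iv,
            _cap(c0.lc_treatment_months_iv, c0.lc_treatment_months_iv_sd),
            1.0, 120.0)
        c.copd_annual = tuple(_gamma(rng, mu, sd)
                              for mu, sd in zip(c0.copd_annual, c0.copd_annual_sd))
        c.exacerbation = _gamma(rng, c0.exacerbation, c0.exacerbation_sd)
        c.statin_annual = _gamma(rng, c0.statin_annual, c0.default_psa_cv * c0.statin_annual)
        c.ace_annual = _gamma(rng, c0.ace_annual, c0.default_psa_cv * c0.ace_annual)
        c.mi = _gamma(rng, c0.mi, c0.mi_sd)
        c.cardiac_arrest_or_angina = _gamma(
            rng, c0.cardiac_arrest_or_angina, c0.cardiac_arrest_or_angina_sd)
        c.stroke_monthly_1_6 = _gamma(rng, c0.stroke_monthly_1_6, c0.stroke_monthly_1_6_sd)
        c.stroke_monthly_7_13 = _gamma(rng, c0.stroke_monthly_7_13, c0.stroke_monthly_7_13_sd)

        u0, u = self.utilities, p.utilities
        u.baseline_le60 = _beta(rng, u0.baseline_le60, u0.baseline_le60_sd)
        u.baseline_60_70 = _beta(rng, u0.baseline_60_70, u0.baseline_60_70_sd)
        u.baseline_gt70 = _beta(rng, u0.baseline_gt70, u0.baseline_gt70_sd)
        u.copd_gold = tuple(_beta(rng, mu, sd)
                            for mu, sd in zip(u0.copd_gold, u0.copd_gold_sd))
        u.lc_stage = tuple(_beta(rng, mu, sd)
                           for mu, sd in zip(u0.lc_stage, u0.lc_stage_sd))
        u.stroke_first_month = _beta(rng, u0.stroke_first_month, u0.stroke_first_month_sd)
        u.stroke_after = _beta(rng, u0.stroke_after, u0.stroke_after_sd)
        u.chd_first_month = _beta(rng, u0.chd_first_month, u0.chd_first_month_sd)
        u.chd_after = _beta(rng, u0.chd_after, u0.chd_after_sd)

        p.require_valid()
        return p


_SECTION_TYPES = {
    "screening": ScreeningParams,
    "lung_cancer": LungCancerParams,
    "copd": CopdParams,
    "cvd": CvdParams,
    "mortality": MortalityParams,
    "cessation": CessationParams,
    "costs": CostTable,
    "utilities": UtilityTable,
    "sim": SimulationParams,
}

_TUPLE_FIELDS = {
    (LungCancerParams, "stage_cutpoints"), (LungCancerParams, "operable_substages"),
    (CopdParams, "prevalence_male"), (CopdParams, "prevalence_female"),
    (CopdParams, "annual_exacerbation_rate"),
    (CopdParams, "hr_mortality_1_2_ci"), (CopdParams, "hr_mortality_3plus_ci"),
    (CvdParams, "chd_type_probs"),
    (CostTable, "copd_annual"), (CostTable, "copd_annual_sd"),
    (UtilityTable, "copd_gold"), (UtilityTable, "copd_gold_sd"),
    (UtilityTable, "lc_stage"), (UtilityTable, "lc_stage_sd"),
}


def _coerce(section: type, name: str, value: Any) -> Any:
    if (section, name) in _TUPLE_FIELDS and isinstance(value, list):
        return tuple(value)
    return value


# ---------------------------------------------------------------------------
# distribution helpers (moment-matched)
# ---------------------------------------------------------------------------



def _cap(mean: float, sd: float) -> float:
    """PSA dispersion for a mean±SD row: quoted SD capped at 20% CV."""
    return min(sd, 0.2 * abs(mean))

def _beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw matched to (mean, capped sd); variance below mean(1-mean)."""
    sd = _cap(mean, sd)
    if sd <= 0:
        return float(mean)
    mean = min(max(mean, 1e-9), 1 - 1e-9)
    var = min(sd * sd, 0.95 * mean * (1 - mean))
    k = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * k, (1 - mean) * k))


def _gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    sd = _cap(mean, sd)
    if mean <= 0 or sd <= 0:
        return float(mean)
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, mean / shape))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Truncated-normal draw by inverse CDF (exact, no rejection loop)."""
    from scipy.stats import norm
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = norm.cdf(lo, mean, sd), norm.cdf(hi, mean, sd)
    return float(norm.ppf(rng.uniform(a, b), mean, sd))


def _sd_from_ci(ci: tuple[float, float]) -> float:
    return (ci[1] - ci[0]) / (2 * 1.959964)


def default_parameters() -> ParameterSet:
    """The shipped base-case parameter set (validated)."""
    return ParameterSet().require_valid()


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def save_parameters(params: ParameterSet, path) -> None:
    d = params.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(_listify(d), fh, sort_keys=False)


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter file; raises with every offending field."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParameterError(f"{path}: not a mapping")
    try:
        p = ParameterSet.from_dict(d)
    except TypeError as e:
        raise ParameterError(f"{path}: {e}") from e
    return p.require_valid()


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
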