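"""Screening strategies, attendance, test performance, referral and cessation."""

import numpy as np
import pytest

import big3sim as b3
from big3sim.params import ParameterError
from big3sim.population import load_attendance_coeffs
from big3sim.screening import (StrategySpec, intercept_only_coeffs,
                               symptomatic_detection_cycle,
                               cessation_probabilities)
from conftest import three_sd_binomial


class TestStrategySpec:
    def test_lc_is_mandatory_for_screening(self):
        with pytest.raises(ParameterError, match="add-on"):
            StrategySpec(diseases=frozenset({"COPD"}))

    def test_names_round_trip(self):
        for name in ("none", "LC", "LC+COPD", "LC+CVD", "Big-3"):
            s = StrategySpec.from_name(name)
            assert StrategySpec.from_name(s.name).diseases == s.diseases
        assert not StrategySpec.from_name("none").screens

    def test_five_default_strategies(self):
        labels = [s.name for s in b3.default_strategies()]
        assert labels == ["No screening", "LC", "LC+COPD", "LC+CVD", "Big-3"]


class TestLdctSensitivity:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0), (2.0, 0.0), (2.999, 0.0),
        (3.0, 0.0), (4.0, 0.5), (4.999, pytest.approx(0.9995)),
        (5.0, 1.0), (6.0, 1.0), (40.0, 1.0),
    ])
    def test_piecewise_values(self, d, expected):
        assert b3.ldct_sensitivity(d) == expected

    def test_continuity_at_breakpoints(self):
        eps = 1e-9
        assert b3.ldct_sensitivity(3 - eps) == pytest.approx(
            b3.ldct_sensitivity(3 + eps), abs=1e-6)
        assert b3.ldct_sensitivity(5 - eps) == pytest.approx(
            b3.ldct_sensitivity(5 + eps), abs=1e-6)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            b3.ldct_sensitivity(-1.0)


class TestAttendance:
    def test_population_mean_near_published_value(self, params, small_cohort):
        df = small_cohort
        coeffs = load_attendance_coeffs()
        for name in ("LC", "LC+CVD", "Big-3"):
            p = b3.attendance_probability(
                df["age"], df["sex"] == "male",
                df["smoking_status"] == "current", df["family_history_lc"],
                df["prior_copd_dx"] | df["prior_cvd"], df["pack_years"],
                StrategySpec.from_name(name), coeffs)
            assert abs(p.mean() - 0.75) < 0.02, name
            assert p.min() >= 0.63 and p.max() <= 0.974

    def test_intercept_only_model_is_constant(self, small_cohort):
        df = small_cohort
        p = b3.attendance_probability(
            df["age"], df["sex"] == "male", df["smoking_status"] == "current",
            df["family_history_lc"], df["prior_cvd"], df["pack_years"],
            StrategySpec.from_name("LC"), intercept_only_coeffs(0.75))
        assert np.allclose(p, 0.75)

    def test_per_strategy_models_are_independent(self, small_cohort):
        """An individual can be likelier to attend LC than Big-3 screening."""
        df = small_cohort
        coeffs = load_attendance_coeffs()
        args = (df["age"], df["sex"] == "male", df["smoking_status"] == "current",
                df["family_history_lc"], df["prior_copd_dx"] | df["prior_cvd"],
                df["pack_years"])
        p_lc = b3.attendance_probability(*args, StrategySpec.from_name("LC"), coeffs)
        p_b3 = b3.attendance_probability(*args, StrategySpec.from_name("Big-3"), coeffs)
        assert (p_lc > p_b3).any() and not np.allclose(p_lc, p_b3)

    def test_unknown_strategy_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            b3.attendance_probability(
                60, True, True, True, False, 40, StrategySpec(),
                load_attendance_coeffs())


class TestCvdReferral:
    def test_ace_fraction_without_history(self, params, rng):
        n = 100_000
        statin, ace = b3.cvd_referral(np.zeros(n, bool), rng.random(n),
                                      rng.random(n), params)
        assert abs(ace.mean() - 0.22) < three_sd_binomial(0.22, n)
        assert abs(statin.mean() - params.screening.statin_prop) \
            < three_sd_binomial(params.screening.statin_prop, n)

    def test_zero_proportions_treat_nobody(self, rng):
        p = b3.default_parameters()
        p.screening.statin_prop = 0.0
        p.screening.ace_prop_no_history = 0.0
        statin, ace = b3.cvd_referral(np.zeros(100, bool), rng.random(100),
                                      rng.random(100), p)
        assert not statin.any() and not ace.any()


class TestCessation:
    def test_with_screening_never_below_without(self):
        p = b3.default_parameters()
        assert cessation_probabilities(p)[1] >= cessation_probabilities(p)[0]
        rng = np.random.default_rng(7)
        for _ in range(200):
            ps = p.sample_psa(rng)
            assert ps.cessation.p_screen >= ps.cessation.p_base

    def test_zero_probabilities_mean_no_quitting(self, small_cohort):
        p = b3.default_parameters()
        p.cessation.p_base = p.cessation.p_screen = 0.0
        rr = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), p,
                             seed=4, horizon_months=60)
        assert rr.counts["quitters"] == 0

    def test_participant_quit_fraction(self, params, small_cohort):
        """Quitters ≈ p_screen among smokers when everyone ever participates."""
        rr = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params,
                             seed=4)
        smokers = rr.counts["smokers_at_start"]
        frac = rr.counts["quitters"] / smokers
        # nearly all smokers participate at least once over 20 annual rounds
        assert abs(frac - params.cessation.p_screen) < 0.03


def test_symptomatic_detection_cycle_inverts_growth():
    vdt = 98.5
    k = symptomatic_detection_cycle(0.33, vdt, 10.0, onset_month=0.0)
    from big3sim.natural_history import tumor_diameter_at
    from big3sim.params import DAYS_PER_MONTH
    assert tumor_diameter_at(0.33, vdt, k * DAYS_PER_MONTH) >= 10.0
    assert tumor_diameter_at(0.33, vdt, (k - 2) * DAYS_PER_MONTH) < 10.0
    assert symptomatic_detection_cycle(0.33, 1e12, 10.0, 0.0) > 1e9  # never grows


def test_false_positive_rate_matches_specificity(params):
    """Scans without a tumour flag positive at ~1 - specificity."""
    p = b3.default_parameters()
    cohort = b3.generate_cohort(b3.CohortConfig(n_individuals=4000, seed=9), p)
    cohort["lc_risk_6y"] = 0.006  # keep tumours rare so most scans are clean
    cohort["lc_risk_6y_former"] = 0.006
    rr = b3.run_strategy(cohort, StrategySpec.from_name("LC"), p, seed=9,
                         horizon_months=120)
    n_scans = rr.counts["scans_without_tumor"]
    fp = rr.counts["false_positives"]
    assert n_scans > 10_000
    assert abs(fp / n_scans - 0.008) < three_sd_binomial(0.008, n_scans)


def test_confusion_matrix_conservation(params, small_cohort):
    rr = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, seed=3)
    c = rr.counts
    assert c["attended_scans"] == c["scans_with_tumor"] + c["scans_without_tumor"]
    assert c["true_positives"] <= c["scans_with_tumor"]
    assert c["false_positives"] <= c["scans_without_tumor"]
    assert c["screen_detected"] == c["true_positives"]
    assert c["lc_dx_lifetime"] == c["screen_detected"] + c["symptomatic_detected"]


def test_lc_only_strategy_triggers_no_copd_or_cvd_findings(params, small_cohort):
    rr_lc = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, seed=3)
    rr_none = b3.run_strategy(small_cohort, StrategySpec(), params, seed=3)
    # no CVD referral treatment beyond background, no screen-triggered COPD dx
    assert rr_lc.counts["statin_ever"] == rr_none.counts["statin_ever"]
    assert rr_lc.counts["ace_ever"] == rr_none.counts["ace_ever"]


def test_stage_shift_with_screening(params, small_cohort):
    """Screening strictly increases the stage-I fraction among diagnoses."""
    r0 = b3.run_strategy(small_cohort, StrategySpec(), params, 3, horizon_months=120)
    r1 = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, 3,
                         horizon_months=120)
    assert r1.stage_distribution_10y["I"] > r0.stage_distribution_10y["I"]


def test_no_screening_rounds_beyond_stop_age(params):
    cohort = b3.generate_cohort(b3.CohortConfig(n_individuals=400, seed=6), params)
    cohort["age"] = 74
    cohort["baseline_utility"] = 0.852
    rr = b3.run_strategy(cohort, StrategySpec.from_name("LC"), params, seed=6,
                         horizon_months=48)
    # only the baseline round is within the age window
    assert rr.counts["invitations"] <= 400
    assert rr.counts["invitations"] > 0
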