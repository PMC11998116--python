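"""Tumour growth, onset, stage model, exacerbations and mortality hazards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import big3sim as b3
from big3sim import natural_history as nh
from big3sim.params import DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# probability conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("p", [0.0, 1.0, 0.01, 0.5, 0.999])
def test_annual_monthly_round_trip(p):
    pm = nh.annual_to_monthly(p)
    assert 0.0 <= pm <= p
    assert nh.monthly_to_annual(pm) == pytest.approx(p, abs=1e-12)


def test_annual_to_monthly_closed_form():
    assert nh.annual_to_monthly(0.01) == pytest.approx(1 - 0.99 ** (1 / 12))


def test_annual_to_monthly_rejects_out_of_range():
    with pytest.raises(ValueError):
        nh.annual_to_monthly(1.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_conversion_round_trips_everywhere(p):
    assert nh.monthly_to_annual(nh.annual_to_monthly(p)) == pytest.approx(p, abs=1e-9)


# ---------------------------------------------------------------------------
# tumour growth law
# ---------------------------------------------------------------------------


def test_diameter_doubles_every_three_vdt():
    assert nh.tumor_diameter_at(0.33, 100.0, 300.0) == pytest.approx(0.66)
    assert nh.tumor_diameter_at(5.0, 98.5, 0.0) == 5.0


def test_growth_law_inversion():
    vdt = np.exp(4.59)
    days = nh.diameter_to_days(0.33, vdt, 3.0)
    assert days == pytest.approx(3 * vdt * np.log2(3.0 / 0.33))
    assert nh.tumor_diameter_at(0.33, vdt, days) == pytest.approx(3.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=0.2, max_value=10.0),
       st.floats(min_value=20.0, max_value=600.0),
       st.integers(min_value=1, max_value=120))
def test_closed_form_growth_equals_monthly_compounding(d0, vdt, months):
    """Closed form vs step-by-step monthly compounding of the growth factor."""
    step = 2.0 ** (DAYS_PER_MONTH / (3.0 * vdt))
    d_iter = d0
    for _ in range(months):
        d_iter *= step
    d_closed = nh.tumor_diameter_at(d0, vdt, months * DAYS_PER_MONTH)
    assert abs(d_closed - d_iter) / d_iter < 1e-9


def test_growth_rejects_bad_inputs():
    with pytest.raises(ValueError):
        nh.tumor_diameter_at(0.33, -5.0, 10.0)
    with pytest.raises(ValueError):
        nh.tumor_diameter_at(0.0, 100.0, 10.0)


# ---------------------------------------------------------------------------
# sampling distributions
# ---------------------------------------------------------------------------


def test_vdt_lognormal_moments(params, rng):
    draws = nh.sample_vdt(params, rng, size=100_000)
    assert (draws > 0).all()
    logs = np.log(draws)
    assert abs(logs.mean() - 4.59) < 3 * 0.2198 / np.sqrt(len(draws))
    assert abs(logs.std() - 0.2198) < 0.005


def test_self_detection_truncated_at_40(params, rng):
    draws = nh.sample_self_detection_diameter(params, rng, size=100_000)
    assert draws.max() <= 40.0
    assert draws.min() > 0.0


def test_self_detection_untruncated_mean_is_shape_over_rate(params, rng):
    draws = nh.sample_self_detection_diameter(params, rng, size=200_000,
                                              cap_mm=np.inf)
    assert draws.mean() == pytest.approx(3.74 / 0.08, rel=0.02)


def test_monthly_onset_probability(params):
    assert nh.monthly_onset_probability(0.0) == 0.0
    assert nh.monthly_onset_probability(0.10068) == pytest.approx(
        1 - 0.89932 ** (1 / 72))


def test_cumulative_onset_recovers_six_year_risk(rng):
    """72 monthly Bernoulli cycles reproduce the 6-year risk."""
    r, n = 0.10068, 100_000
    pm = nh.monthly_onset_probability(r)
    onset = (rng.random((n, 72)) < pm).any(axis=1)
    assert abs(onset.mean() - r) < 3 * np.sqrt(r * (1 - r) / n)


# ---------------------------------------------------------------------------
# stage at detection
# ---------------------------------------------------------------------------


def test_stage_model_stochastically_monotone(params):
    lc = params.lung_cancer
    p10 = nh.stage_group_probs(10.0, lc)
    p40 = nh.stage_group_probs(40.0, lc)
    assert p40[2] + p40[3] >= p10[2] + p10[3]  # P(stage >= III)
    assert np.allclose(p10.sum(), 1) and np.allclose(p40.sum(), 1)


def test_stage_model_degenerate_all_stage_ia(params):
    lc = b3.default_parameters().lung_cancer
    lc.stage_cutpoints = (1e9, 2e9, 3e9)
    u = np.linspace(0.01, 0.99, 50)
    sub = nh.stage_at_detection(np.full(50, 5.0), lc, u)
    assert (sub == b3.SUBSTAGES.index("IA")).all()


def test_small_screen_detected_tumour_is_usually_stage_i(params, rng):
    sub = nh.stage_at_detection(np.full(5000, 5.0), params.lung_cancer,
                                rng.random(5000))
    group = nh.substage_to_group(sub)
    assert (group == 0).mean() > 0.8


def test_substage_diameter_rule(params):
    lc = params.lung_cancer
    # force stage group I via tiny u, then the IA/IB split is by diameter
    sub_small = nh.stage_at_detection(10.0, lc, 0.001)
    sub_large = nh.stage_at_detection(35.0, lc, 0.001)
    assert b3.SUBSTAGES[sub_small] == "IA"
    assert b3.SUBSTAGES[sub_large] == "IB"


# ---------------------------------------------------------------------------
# COPD
# ---------------------------------------------------------------------------


def test_exacerbation_rate_table_and_relative_risks(params):
    mu_mild = nh.monthly_exacerbation_rate(1, False, False, params)
    assert mu_mild == pytest.approx(0.754 / 12)
    mu_both = nh.monthly_exacerbation_rate(1, True, True, params)
    assert mu_both == pytest.approx(0.754 / 12 * 0.82 * 0.78)
    assert nh.monthly_exacerbation_rate(0, False, False, params) == 0.0


def test_simulated_exacerbation_rate_recovery(params, rng):
    """10^5 person-years of monthly Poisson draws recover the annual rates."""
    n_years = 100_000
    for sev in (1, 4):
        rate = params.copd.annual_exacerbation_rate[sev]
        mu = nh.monthly_exacerbation_rate(sev, False, False, params)
        counts = rng.poisson(mu, size=(n_years, 12)).sum()
        assert abs(counts / n_years - rate) < 3 * np.sqrt(rate / n_years)


def test_copd_death_hazard_ratio_structure(params):
    p0 = nh.copd_death_prob(0, params)
    p3 = nh.copd_death_prob(3, params)
    assert np.log1p(-p3) / np.log1p(-p0) == pytest.approx(4.13)
    assert nh.copd_death_prob(1, params) == nh.copd_death_prob(2, params)
    assert nh.copd_death_prob(5, params, base_monthly_hazard=0.0) == 0.0


# ---------------------------------------------------------------------------
# lung-cancer survival
# ---------------------------------------------------------------------------


def test_lc_death_prob_limits(params):
    p = b3.default_parameters()
    p.lung_cancer.gompertz_b["IV"] = 0.0
    assert nh.lc_death_prob(b3.SUBSTAGES.index("IV"), 5, p) == 0.0
    p.lung_cancer.gompertz_b["IV"] = 0.2
    p.lung_cancer.gompertz_c["IV"] = 0.0
    assert nh.lc_death_prob(b3.SUBSTAGES.index("IV"), 7, p) == pytest.approx(
        1 - np.exp(-0.2))


def test_lc_death_requires_stage(params):
    with pytest.raises(ValueError):
        nh.lc_death_prob(-1, 0, params)


def test_gompertz_median_survival_closed_form_vs_simulation(rng):
    """Choose (c, b) with closed-form median 12 months; simulate and compare."""
    c = -0.05
    b = np.log(2) * (-c) / (1 - np.exp(c * 12))
    assert nh.gompertz_median_survival(c, b) == pytest.approx(12.0)
    n = 100_000
    E = rng.exponential(size=n)
    months = np.arange(0, 600)
    cum = b * (np.exp(c * (months + 1)) - np.exp(c * months)) / c
    cum = np.cumsum(cum)
    death_month = np.searchsorted(cum, E)  # first cycle the budget is exceeded
    died = death_month < len(months)
    # overall survival median: survivors (cure fraction) count as infinite
    times = np.where(died, death_month + 1.0, np.inf)
    assert abs(np.median(times) - 12.0) <= 1.0


def test_gompertz_cure_fraction():
    # negative c with b/|c| < ln 2 never reaches median survival
    assert nh.gompertz_median_survival(-0.1, 0.05) == np.inf
    assert nh.gompertz_median_survival(0.0, 0.1) == pytest.approx(np.log(2) / 0.1)
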