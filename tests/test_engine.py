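"""Engine orchestration: determinism, conservation, CRN, accrual, warm-up."""

import numpy as np
import pytest

import big3sim as b3
from big3sim.engine import draw_latents, resolve_death, warmup, _poisson_icdf
from big3sim.screening import StrategySpec


def test_bit_identical_reruns(params, small_cohort):
    a = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, seed=17)
    b = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, seed=17)
    assert a.mean_cost == b.mean_cost
    assert a.mean_qaly == b.mean_qaly
    assert a.counts == b.counts
    c = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), params, seed=18)
    assert c.mean_cost != a.mean_cost


def test_population_conservation(params, small_cohort):
    rr = b3.run_strategy(small_cohort, StrategySpec(), params, seed=5,
                         record_ledger=True)
    n = len(small_cohort)
    # everyone eventually dies (age-100 cap) and deaths partition the cohort
    assert rr.counts["deaths_total"] == n
    per = rr.per_individual
    assert set(per["cause"]) <= {"other", "lc", "copd", "cvd"}
    # no accrual after death: utility rows are zero from the death cycle on
    died_at = per["death_month"].to_numpy()
    util = rr.ledger["utility"]
    for i in (0, 7, 100, n - 1):
        assert (util[i, died_at[i]:] == 0).all()


def test_ledger_additivity(params, small_cohort):
    rr = b3.run_strategy(small_cohort.iloc[:300], StrategySpec.from_name("Big-3"),
                         params, seed=5, record_ledger=True)
    led = rr.ledger
    cost = (led["cost"].astype(float) * led["df_cost"][None, :]).sum(axis=1)
    qaly = (led["utility"].astype(float) / 12.0 * led["df_effect"][None, :]).sum(axis=1)
    assert np.allclose(cost, led["cost_total"], rtol=1e-6)
    assert np.allclose(qaly, led["qaly_total"], rtol=1e-6)
    assert rr.mean_cost == pytest.approx(led["cost_total"].mean())


def test_common_random_numbers_across_strategies(params, small_cohort):
    """Latent histories depend only on the seed, never on the strategy."""
    lat1 = draw_latents(100, 540, 20, params, seed=9)
    lat2 = draw_latents(100, 540, 20, params, seed=9)
    assert np.array_equal(lat1.vdt1, lat2.vdt1)
    assert np.array_equal(lat1.thr1, lat2.thr1)
    assert np.array_equal(lat1.E_onset1, lat2.E_onset1)

    # a screening arm whose test never fires and whose extras cost nothing
    # must reproduce the no-screening arm outcome for outcome equality
    p = b3.default_parameters()
    p.cessation.p_screen = p.cessation.p_base
    p.screening.sens_d_lo = 1e8
    p.screening.sens_d_hi = 1e9
    p.screening.specificity = 1.0
    p.costs.invitation = 0.0
    p.costs.ldct_scan = 0.0
    r_none = b3.run_strategy(small_cohort, StrategySpec(), p, seed=9)
    r_sham = b3.run_strategy(small_cohort, StrategySpec.from_name("LC"), p, seed=9)
    assert r_sham.mean_qaly == pytest.approx(r_none.mean_qaly, rel=1e-12)
    assert r_sham.mean_cost == pytest.approx(r_none.mean_cost, rel=1e-12)
    assert r_sham.counts["lc_cases_lifetime"] == r_none.counts["lc_cases_lifetime"]


def test_discounted_life_expectancy_closed_form(params):
    """Flat other-cause hazard only: QALYs equal the discounted annuity."""
    p = b3.default_parameters()
    p.mortality.other_cause_log_slope = 0.0  # flat hazard
    p.copd.base_monthly_hazard = 0.0
    p.cessation.p_base = p.cessation.p_screen = 0.0
    for f in ("baseline_le60", "baseline_60_70", "baseline_gt70"):
        setattr(p.utilities, f, 1.0)
    p.utilities.copd_gold = (1.0,) * 4
    p.screening.background_statin_history = 0.0
    p.screening.background_ace_history = 0.0
    n = 20_000
    cohort = b3.generate_cohort(b3.CohortConfig(n_individuals=n, seed=21), p)
    cohort["lc_risk_6y"] = 0.0
    cohort["lc_risk_6y_former"] = 0.0
    cohort["chd_risk_annual"] = 0.0
    cohort["chd_risk_annual_former"] = 0.0
    cohort["stroke_risk_annual"] = 0.0
    cohort["stroke_risk_annual_former"] = 0.0
    cohort["emphysema_severity"] = "none"
    cohort["exacerbation_group"] = 0
    rr = b3.run_strategy(cohort, StrategySpec(), p, seed=21)
    pm = 1 - (1 - p.mortality.other_cause_annual) ** (1 / 12)
    surv_factor = 1 - pm
    expected = 0.0
    for age0, cnt in cohort["age"].value_counts().items():
        cap = (p.sim.max_age - age0) * 12
        t = np.arange(cap)
        # utility accrues for survivors of each cycle
        expected += cnt * np.sum(surv_factor ** (t + 1)
                                 * 1.015 ** (-t / 12) / 12.0)
    expected /= n
    assert rr.mean_cost == 0.0
    assert rr.mean_qaly == pytest.approx(expected, rel=0.01)


class TestResolveDeath:
    def test_trivial_cases(self, rng):
        assert resolve_death({c: 0.0 for c in ("other", "lc", "copd", "cvd")},
                             rng=rng) is None
        assert resolve_death({"lc": 1.0}, rng=rng) == "lc"

    def test_precedence_when_multiple_fire(self):
        u = {"other": 0.9, "lc": 0.0, "copd": 0.0, "cvd": 0.0}
        assert resolve_death({"lc": 0.5, "copd": 0.5, "cvd": 0.5},
                             u={"other": 0.5, "lc": 0.1, "copd": 0.1, "cvd": 0.1}) == "lc"

    def test_cause_frequencies_match_product_formula(self, rng):
        """Cause i frequency = p_i * prod_{j earlier}(1 - p_j)."""
        probs = {"other": 0.02, "lc": 0.05, "copd": 0.03, "cvd": 0.04}
        n = 100_000
        counts = {c: 0 for c in probs}
        none = 0
        for _ in range(n):
            c = resolve_death(probs, rng=rng)
            if c is None:
                none += 1
            else:
                counts[c] += 1
        expected = {}
        acc = 1.0
        for c in ("other", "lc", "copd", "cvd"):
            expected[c] = probs[c] * acc
            acc *= 1 - probs[c]
        for c, e in expected.items():
            assert abs(counts[c] / n - e) < 3 * np.sqrt(e * (1 - e) / n), c
        assert abs(none / n - acc) < 3 * np.sqrt(acc * (1 - acc) / n)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            resolve_death({"lc": 1.2}, rng=rng)


class TestWarmup:
    def test_zero_months_no_prevalent_tumours(self, params):
        lat = draw_latents(500, 540, 20, params, seed=3)
        wu = warmup(np.full(500, 1e-3), 0, lat, params)
        assert not wu.present.any()
        assert not wu.removed.any()

    def test_oversized_warmup_tumours_removed(self, params):
        p = b3.default_parameters()
        lat = draw_latents(2000, 540, 20, p, seed=3)
        lat.thr1[:] = p.lung_cancer.start_diameter_mm  # everything instantly detectable
        wu = warmup(np.full(2000, 1e-2), 240, lat, p)
        assert not wu.present.any()
        assert wu.removed.sum() > 0
        # removed individuals draw their next tumour from the second latent slot
        assert (wu.E_remaining[wu.removed] == lat.E_onset2[wu.removed]).all()

    def test_prevalent_tumours_are_undetected(self, params):
        lat = draw_latents(5000, 540, 20, params, seed=3)
        wu = warmup(np.full(5000, 1.3e-3), params.sim.warmup_months, lat, params)
        assert wu.present.sum() > 0
        d0 = params.lung_cancer.start_diameter_mm
        from big3sim.params import DAYS_PER_MONTH
        d = d0 * 2 ** (-wu.onset_month[wu.present] * DAYS_PER_MONTH
                       / (3 * lat.vdt1[wu.present]))
        assert (d < lat.thr1[wu.present]).all()

    def test_negative_months_rejected(self, params):
        lat = draw_latents(10, 540, 20, params, seed=3)
        with pytest.raises(ValueError):
            warmup(np.full(10, 1e-3), -1, lat, params)


def test_poisson_icdf_matches_scipy():
    from scipy.stats import poisson
    rng = np.random.default_rng(0)
    u = rng.random(20_000)
    for mu in (0.01, 0.06, 0.11):
        mine = _poisson_icdf(u, np.full_like(u, mu))
        ref = poisson.ppf(u, mu)
        assert np.array_equal(mine, ref.astype(int))


def test_intermediate_outcomes_structure(params, small_cohort):
    rr = b3.run_strategy(small_cohort, StrategySpec.from_name("LC+CVD"), params,
                         seed=2, horizon_months=120)
    from big3sim.engine import intermediate_outcomes
    out = intermediate_outcomes(rr)
    assert out["total_deaths_10y"] == (out["lc_deaths_10y"] + out["copd_deaths_10y"]
                                       + out["cvd_deaths_10y"] + out["other_deaths_10y"])
    stages = [out[f"stage_{g}_pct_10y"] for g in b3.STAGE_GROUPS]
    assert sum(stages) == pytest.approx(100.0, abs=0.1)
    assert all(v >= 0 for v in out.values())
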