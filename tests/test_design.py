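import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from monalloc.design import (
    CostModel,
    PowerSpec,
    T_FIXED,
    budget_for_portfolio,
    ci_percent,
    cost_for_precision,
    min_n_for_power,
    power_curve,
    power_one_sample,
    stations_for_precision,
    stations_from_budget,
    survey_cost,
)
from monalloc.errors import DesignError

MODEL = CostModel()  # A=1, B=20, n=3, sum(m)=0.1, N_time=12

# between-station CVs of the six time-integrated variables (pilot constants)
CVS = {
    "salinity": 6.21,
    "temperature": 0.97,
    "par": 12.36,
    "oxygen": 0.55,
    "cdom": 10.83,
    "chlorophyll": 4.76,
}


def power_oracle(n, d, alpha=0.05):
    """Independent noncentral-t power computation (kept free of design.py)."""
    n = np.asarray(n, dtype=float)
    tc = stats.t.isf(alpha / 2, n - 1)
    nc = d * np.sqrt(n)
    # far lower tail may underflow to nan in scipy; its true mass is ~0
    lower = np.nan_to_num(stats.nct.cdf(-tc, n - 1, nc), nan=0.0)
    return stats.nct.sf(tc, n - 1, nc) + lower


class TestCostModel:
    def test_fixed_cost_only(self):
        assert survey_cost(MODEL, 0) == pytest.approx(20.0)

    def test_budget_of_28_units(self):
        assert survey_cost(MODEL, 1.53846) == pytest.approx(28.0, abs=0.05)

    def test_hand_product(self):
        m = CostModel(A=0, B=0, n=1, m=(1.0,), N_time=2)
        assert survey_cost(m, 3) == pytest.approx(6.0)

    def test_stations_from_budget(self):
        assert stations_from_budget(MODEL, 28.0) == pytest.approx(1.53846, abs=1e-4)
        one_station_budget = MODEL.B + MODEL.N_time * MODEL.per_station_cost
        assert stations_from_budget(MODEL, one_station_budget) == pytest.approx(1.0)

    def test_budget_below_fixed_costs(self):
        with pytest.raises(DesignError, match="below fixed costs"):
            stations_from_budget(MODEL, 19.9)

    def test_invalid_model(self):
        with pytest.raises(DesignError):
            CostModel(n=0)

    @settings(deadline=None, max_examples=100)
    @given(
        budget=st.floats(20.01, 1e4),
        a=st.floats(0, 50),
        b=st.floats(0, 20),
        n=st.floats(0.5, 10),
        nt=st.integers(1, 52),
    )
    def test_round_trip_identity(self, budget, a, b, n, nt):
        model = CostModel(A=a, B=b, n=n, m=(0.05, 0.05), N_time=nt)
        if budget <= model.B:
            return
        n_space = stations_from_budget(model, budget)
        assert survey_cost(model, n_space) == pytest.approx(budget, rel=1e-10)


class TestPrecision:
    def test_salinity_prefactor(self):
        # t * CV% at N = 1 gives the CI% prefactor 12.48
        assert ci_percent(6.21, 1) == pytest.approx(12.48, abs=0.005)

    def test_zero_cv(self):
        assert ci_percent(0.0, 9) == 0.0

    def test_par_at_25_stations_meets_5pct(self):
        assert ci_percent(12.36, 25) == pytest.approx(2.01 * 12.36 / 5, rel=1e-12)
        assert ci_percent(12.36, 25) <= 5

    def test_exact_df_mode(self):
        expect = stats.t.ppf(0.975, 20) * 6.21 / math.sqrt(21)
        assert ci_percent(6.21, 21, "exact_df") == pytest.approx(expect, rel=1e-12)
        with pytest.raises(DesignError):
            ci_percent(6.21, 1.5, "exact_df")

    def test_halves_when_n_quadruples(self):
        assert ci_percent(10.0, 36) == pytest.approx(ci_percent(10.0, 9) / 2, rel=1e-12)

    @pytest.mark.parametrize("cv, target, expected", [(12.36, 5, 25), (10.83, 5, 19)])
    def test_stations_for_precision(self, cv, target, expected):
        assert stations_for_precision(cv, target) == expected

    def test_one_station_suffices_for_loose_target(self):
        assert stations_for_precision(4.0, T_FIXED * 4.0 + 0.1) == 1

    def test_stations_quadruple_when_target_halves(self):
        n1 = (T_FIXED * 10.0 / 5.0) ** 2  # continuous counts: exactly x4
        n2 = (T_FIXED * 10.0 / 2.5) ** 2
        assert n2 == pytest.approx(4 * n1, rel=1e-12)
        assert stations_for_precision(10.0, 2.5) == math.ceil(n2)

    def test_exact_df_scan_matches_definition(self):
        n = stations_for_precision(8.0, 4.0, "exact_df")
        assert ci_percent(8.0, n, "exact_df") <= 4.0
        assert ci_percent(8.0, n - 1, "exact_df") > 4.0


class TestCostForPrecision:
    def test_20pct_precision_costs_28(self):
        cost = cost_for_precision(MODEL, 12.36, 20.0, continuous=True)
        assert cost == pytest.approx(28.02, abs=0.05)
        assert round(cost) == 28

    def test_loose_target_approaches_fixed_cost(self):
        assert cost_for_precision(MODEL, 12.36, 1e9) == pytest.approx(MODEL.B, abs=1e-6)

    def test_near_one_station(self):
        cost = cost_for_precision(MODEL, 4.76, 9.56, continuous=True)
        n_space = (T_FIXED * 4.76 / 9.56) ** 2
        assert n_space == pytest.approx(1.0016, abs=1e-3)
        assert cost == pytest.approx(survey_cost(MODEL, n_space), rel=1e-12)

    def test_integer_mode_at_least_continuous(self):
        cont = cost_for_precision(MODEL, 10.83, 5.0, continuous=True)
        integer = cost_for_precision(MODEL, 10.83, 5.0, continuous=False)
        assert integer >= cont

    def test_round_trip_with_implied_ci(self):
        # cost at the CI implied by a given N_space returns the original cost
        for n_space in (0.7, 1.53846, 9.2):
            implied_ci = ci_percent(10.83, n_space)
            cost = cost_for_precision(MODEL, 10.83, implied_ci, continuous=True)
            assert cost == pytest.approx(survey_cost(MODEL, n_space), rel=1e-10)


class TestPortfolio:
    def test_budget_for_all_six_variables_at_20pct(self):
        pb = budget_for_portfolio(MODEL, CVS, 20.0)
        assert pb.budget == 28
        assert pb.worst_cv == 12.36
        assert pb.n_space == pytest.approx(1.543, abs=1e-3)

    def test_achieved_ci_for_best_variable(self):
        pb = budget_for_portfolio(MODEL, CVS, 20.0)
        # oxygen (CV 0.55): 2.01*0.55/sqrt(n_space)
        assert pb.achieved_ci["oxygen"] == pytest.approx(0.89, abs=0.01)

    def test_single_variable_at_n_equal_one(self):
        cv = 5.0
        pb = budget_for_portfolio(MODEL, {"x": cv}, T_FIXED * cv)
        assert pb.n_space == pytest.approx(1.0, rel=1e-12)
        assert pb.budget_exact == pytest.approx(MODEL.B + MODEL.N_time * MODEL.per_station_cost)

    def test_empty_portfolio(self):
        with pytest.raises(DesignError):
            budget_for_portfolio(MODEL, {}, 20.0)


class TestPower:
    def test_null_effect_gives_alpha(self):
        spec = PowerSpec(delta_percent=0.0, cv_percent=5.0)
        assert power_one_sample(30, spec) == pytest.approx(0.05, abs=1e-9)

    def test_chlorophyll_minimality_at_10(self):
        spec = PowerSpec(delta_percent=5.0, cv_percent=4.76)
        assert power_one_sample(10, spec) >= 0.8
        assert power_one_sample(9, spec) < 0.8

    def test_small_n_rejected(self):
        with pytest.raises(DesignError):
            power_one_sample(1, PowerSpec(delta_percent=5, cv_percent=5))

    @pytest.mark.parametrize(
        "cv, delta, expected",
        [
            (4.76, 5, 10), (6.21, 5, 15), (10.83, 5, 39), (12.36, 5, 50),
            (4.76, 10, 5), (6.21, 10, 6), (10.83, 10, 12), (12.36, 10, 15),
        ],
    )
    def test_min_n_matches_published_sample_sizes(self, cv, delta, expected):
        assert min_n_for_power(PowerSpec(delta_percent=delta, cv_percent=cv)) == expected

    def test_huge_effect_floors_at_2(self):
        # at d = 10 the heavy-tailed df = 1 denominator still caps power at
        # 0.73 for n = 2, so the search floor is only reached for much larger
        # standardized effects
        assert min_n_for_power(PowerSpec(delta_percent=100, cv_percent=10)) == 3
        assert min_n_for_power(PowerSpec(delta_percent=10000, cv_percent=10)) == 2

    def test_min_n_agrees_with_brute_force_scan(self):
        for d in np.arange(0.1, 3.01, 0.1):
            spec = PowerSpec(delta_percent=d * 10, cv_percent=10.0)
            ns = np.arange(2, 5001)
            powers = power_oracle(ns, d)
            brute = int(ns[np.argmax(powers >= 0.8)])
            assert min_n_for_power(spec) == brute

    def test_power_curve_monotone_and_crossing(self):
        spec = PowerSpec(delta_percent=5.0, cv_percent=10.83)
        curve = dict(power_curve(spec, 60))
        vals = list(curve.values())
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert curve[38] < 0.8 <= curve[39]

    def test_saturates_quickly_for_large_effect(self):
        spec = PowerSpec(delta_percent=100.0, cv_percent=10.0)
        assert power_one_sample(5, spec) > 0.999

    def test_rejection_rate_matches_analytic_power(self):
        # simulated one-sample t tests at the minimal n for two design points
        rng = np.random.default_rng(20260928)
        reps = 10_000
        for cv, delta in ((4.76, 5.0), (10.83, 10.0)):
            spec = PowerSpec(delta_percent=delta, cv_percent=cv)
            n = min_n_for_power(spec)
            x = rng.normal(spec.d, 1.0, size=(reps, n))
            t_stat = x.mean(axis=1) / (x.std(axis=1, ddof=1) / math.sqrt(n))
            crit = stats.t.ppf(0.975, n - 1)
            rate = float(np.mean(np.abs(t_stat) > crit))
            assert rate == pytest.approx(power_one_sample(n, spec), abs=0.02)

    def test_invalid_specs(self):
        with pytest.raises(DesignError):
            PowerSpec(delta_percent=5, cv_percent=5, alpha=1.5)
        with pytest.raises(DesignError):
            PowerSpec(delta_percent=5, cv_percent=0)
        with pytest.raises(DesignError):
            min_n_for_power(PowerSpec(delta_percent=0.0, cv_percent=5.0))
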