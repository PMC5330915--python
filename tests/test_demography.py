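"""Demographic trajectory analysis: rates, baselines, recovery, comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from coraldemog import demography as dg


def exponential_table(rate_pct_per_year, months=(0, 6, 9), a0=100.0, **kw):
    areas = {m: a0 * (1 + rate_pct_per_year / 100.0) ** (m / 12.0) for m in months}
    return areas


class TestSizeClasses:
    def test_mean_split_with_tie_going_small(self, make_colony_table):
        table = make_colony_table({"a": {0: 100}, "b": {0: 200}, "c": {0: 300}})
        sized = dg.assign_size_classes(table)
        by = sized.set_index("colony_id")["size_class"]
        assert by["c"] == "large"
        assert by["a"] == "small" and by["b"] == "small"  # tie at the mean -> small

    def test_study_sized_fixture_reproduces_split_counts(self, make_colony_table):
        # 52 colonies, 20 well below / 32 above the sample mean
        colonies = {f"s{i}": {0: 100.0} for i in range(20)}
        colonies.update({f"l{i}": {0: 700.0} for i in range(32)})
        sized = dg.assign_size_classes(make_colony_table(colonies))
        counts = sized[sized["month"] == 0]["size_class"].value_counts()
        assert counts["large"] == 32 and counts["small"] == 20

    def test_degenerate_equal_areas_warns_all_small(self, make_colony_table):
        table = make_colony_table({c: {0: 150.0} for c in "abc"})
        with pytest.warns(UserWarning, match="degenerate"):
            sized = dg.assign_size_classes(table)
        assert (sized["size_class"] == "small").all()


class TestPercentOfBaseline:
    def test_identity_at_baseline(self, make_colony_table):
        table = make_colony_table({"a": {0: 120.0, 9: 80.0}})
        assert dg.percent_of_baseline(table, 0) == pytest.approx(100.0)

    def test_printed_group_totals(self):
        assert dg.percent_of_baseline_totals(19975.11, 27699.51) == pytest.approx(
            72.11, abs=0.005
        )
        assert dg.percent_of_baseline_totals(5053.71, 16318.98) == pytest.approx(
            30.97, abs=0.005
        )

    def test_invariant_under_uniform_rescaling(self, make_colony_table):
        colonies = {f"c{i}": {0: 50.0 + 30 * i, 9: 40.0 + 25 * i} for i in range(5)}
        t1 = make_colony_table(colonies)
        t2 = t1.assign(live_area_cm2=t1["live_area_cm2"] * 3.7)
        assert dg.percent_of_baseline(t1, 9) == pytest.approx(
            dg.percent_of_baseline(t2, 9)
        )

    def test_death_never_increases_percent(self, make_colony_table):
        colonies = {"a": {0: 100.0, 9: 90.0}, "b": {0: 50.0, 9: 60.0}}
        before = dg.percent_of_baseline(make_colony_table(colonies), 9)
        colonies["b"][9] = 0.0  # colony b dies
        after = dg.percent_of_baseline(make_colony_table(colonies), 9)
        assert after < before

    def test_lost_colony_excluded_from_both_sums(self, make_colony_table):
        colonies = {"a": {0: 100.0, 9: 50.0}, "b": {0: 900.0}}  # b lost after month 0
        assert dg.percent_of_baseline(make_colony_table(colonies), 9) == pytest.approx(50.0)

    def test_zero_baseline_errors(self, make_colony_table):
        table = make_colony_table({"a": {0: 0.0, 9: 0.0}})
        with pytest.raises(dg.UndefinedBaselineError):
            dg.percent_of_baseline(table, 9)


class TestRates:
    @pytest.mark.parametrize(
        "a0, a1, months, expected",
        [
            (100.0, 50.0, 12, -50.0),
            (123.4, 123.4, 34, 0.0),
            (100.0, 110.0, 24, 4.881),
            (100.0, 0.0, 9, -100.0),
        ],
        ids=["halving", "identity", "slow-growth", "death"],
    )
    def test_endpoint_rate(self, a0, a1, months, expected):
        assert dg.annualized_rate_endpoint(a0, a1, months) == pytest.approx(
            expected, abs=5e-4
        )

    def test_endpoint_requires_positive_start(self):
        with pytest.raises(dg.DemographyError):
            dg.annualized_rate_endpoint(0.0, 10.0, 12)

    @pytest.mark.parametrize("rate", [-56.6, -40.3, -1.66, 2.23])
    def test_regression_recovers_noisefree_rate(self, rate):
        months = (0, 6, 9)
        areas = [100.0 * (1 + rate / 100.0) ** (m / 12.0) for m in months]
        est, method = dg.annualized_rate_regression(months, areas)
        assert method == "regression"
        assert est == pytest.approx(rate, abs=1e-9)
        assert dg.annualized_rate_endpoint(areas[0], areas[-1], 9) == pytest.approx(
            est, abs=1e-9
        )

    def test_constant_trajectory_rate_zero(self):
        est, _ = dg.annualized_rate_regression((22, 34, 46, 58), [75.0] * 4)
        assert est == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rate=st.floats(-90.0, 150.0),
        a0=st.floats(10.0, 5000.0),
        nm=st.integers(3, 9),
    )
    def test_endpoint_and_regression_agree_on_exponentials(self, rate, a0, nm):
        months = dg.OBSERVATION_MONTHS[:nm]
        areas = [a0 * (1 + rate / 100.0) ** (m / 12.0) for m in months]
        reg, method = dg.annualized_rate_regression(months, areas)
        end = dg.annualized_rate_endpoint(areas[0], areas[-1], months[-1])
        assert method == "regression"
        assert math.isclose(reg, end, rel_tol=1e-9, abs_tol=1e-9)
        assert math.isclose(reg, rate, rel_tol=1e-7, abs_tol=1e-7)

    def test_two_points_fall_back_to_endpoint(self):
        est, method = dg.annualized_rate_regression((0, 9), [100.0, 80.0])
        assert method == "endpoint"
        assert est == pytest.approx(dg.annualized_rate_endpoint(100, 80, 9))


class TestGroupRate:
    def test_symmetric_rates_average_to_zero(self, make_colony_table):
        colonies = {
            "up": exponential_table(10.0),
            "down": exponential_table(-10.0),
        }
        table = make_colony_table(colonies)
        est = dg.group_rate(table, dg.DEFAULT_PERIODS.response, aggregate="arithmetic")
        assert est.rate_pct_per_year == pytest.approx(0.0, abs=1e-9)
        # sample sd of {+10, -10} is sqrt(200); SE = sqrt(200)/sqrt(2) = 10
        assert est.se_pct == pytest.approx(10.0, abs=1e-6)

    def test_identical_trajectories_have_zero_se(self, make_colony_table):
        colonies = {f"c{i}": exponential_table(-20.0) for i in range(5)}
        est = dg.group_rate(make_colony_table(colonies), dg.DEFAULT_PERIODS.response)
        assert est.rate_pct_per_year == pytest.approx(-20.0, abs=1e-9)
        assert est.se_pct == pytest.approx(0.0, abs=1e-9)

    def test_dead_colony_excluded_by_default_included_on_request(self, make_colony_table):
        colonies = {
            "alive": exponential_table(0.0),
            "dead": {0: 100.0, 6: 40.0, 9: 0.0},
        }
        table = make_colony_table(colonies)
        est = dg.group_rate(table, dg.DEFAULT_PERIODS.response)
        assert est.n_colonies == 1
        est2 = dg.group_rate(table, dg.DEFAULT_PERIODS.response, include_dead=True)
        assert est2.n_colonies == 2
        assert est2.rate_pct_per_year == pytest.approx(-50.0)
        assert est2.method == "mixed"

    def test_group_percent_change_matches_hand_mean(self, make_colony_table):
        colonies = {"a": {0: 100.0, 9: 80.0}, "b": {0: 200.0, 9: 100.0}}
        mean, se, n = dg.group_percent_change(make_colony_table(colonies))
        assert n == 2
        assert mean == pytest.approx((-20.0 + -50.0) / 2)

    def test_empty_group_raises(self, make_colony_table):
        table = make_colony_table({"a": {0: 100.0}})  # no later observations
        with pytest.raises(dg.DemographyError):
            dg.group_rate(table, dg.DEFAULT_PERIODS.recovery)


class TestRecoveryTime:
    def test_exact_parabola_vertex(self):
        months = np.array([0, 6, 9, 22, 34, 46, 58], float)
        values = 0.03 * (months - 30.0) ** 2 + 60.0
        est = dg.recovery_time(months, values)
        assert est.t_star_months == pytest.approx(30.0, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not est.extrapolated

    def test_linear_decline_has_no_curvature(self):
        months = np.array([0, 6, 9, 22, 34, 46, 58], float)
        est = dg.recovery_time(months, 100.0 - 0.5 * months)
        assert est.t_star_months is None

    def test_vertex_outside_span_is_flagged_extrapolated(self):
        months = np.array([0.0, 6.0, 9.0, 22.0])
        values = 0.05 * (months - 40.0) ** 2 + 50.0
        est = dg.recovery_time(months, values)
        assert est.extrapolated

    def test_bootstrap_interval_brackets_noisy_vertex(self):
        rng = np.random.default_rng(4)
        months = np.arange(0, 59, 2.0)
        values = 64.0 + 0.02 * (months - 33.6) ** 2 + rng.normal(0, 2.5, len(months))
        est, (lo, hi), samples = dg.recovery_time_bootstrap(months, values, seed=9)
        assert lo < est.t_star_months < hi
        assert lo < 33.6 < hi


class TestHorizon:
    @pytest.mark.parametrize(
        "start, rate, target, expected",
        [
            (1.0, 100.0, 2.0, 1.0),
            (0.6374, 2.23, 1.0, 20.4),
            (1.0, -3.55, 0.5, 19.2),
        ],
        ids=["doubling", "regrow-to-baseline", "decline-to-half"],
    )
    def test_closed_form(self, start, rate, target, expected):
        est = dg.horizon_years(start, rate, target)
        assert est.years == pytest.approx(expected, abs=0.05)
        assert est.reachable

    def test_wrong_sign_is_unreachable(self):
        est = dg.horizon_years(0.6, -5.0, 1.0)
        assert not est.reachable
        assert math.isinf(est.years)

    def test_rate_at_or_below_total_loss_rejected(self):
        with pytest.raises(dg.DemographyError):
            dg.horizon_years(1.0, -100.0, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        start=st.floats(0.05, 0.95),
        rate=st.floats(0.5, 50.0),
        target=st.floats(1.0, 2.0),
    )
    def test_agrees_with_iterative_compounding_oracle(self, start, rate, target):
        est = dg.horizon_years(start, rate, target)
        hi = 2.0 * est.years + 10.0
        oracle = brentq(
            lambda y: start * (1 + rate / 100.0) ** y - target, 0.0, hi, xtol=1e-9
        )
        assert est.years == pytest.approx(oracle, abs=1e-6)


class TestSizeClassComparison:
    def test_textbook_pair(self):
        res = dg.compare_size_classes([1, 2, 3], [4, 5, 6])
        assert res.t_stat == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4
        assert res.significant

    def test_identical_samples_are_null(self):
        res = dg.compare_size_classes([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.t_stat == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_pooled_vs_welch_df(self):
        large = [1.0, 2.0, 3.0, 4.0]
        small = [2.0, 4.0, 6.0]
        pooled = dg.compare_size_classes(large, small)
        welch = dg.compare_size_classes(large, small, welch=True)
        assert pooled.df == 5
        assert welch.df != pooled.df
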