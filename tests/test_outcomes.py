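"""Survival analysis, free days, EASIX and class summary tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenolca import cohort
from phenolca.outcomes import (
    class_summary,
    easix,
    free_days,
    km_estimate,
    logrank_test,
    proportional_hazards,
)


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        curve = km_estimate([10, 20, 30], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_hand_worked_product_limit(self):
        # times (1,2,3) events (1,0,1): S(1) = 2/3, S(3) = 2/3 * 0 = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3) == pytest.approx(0.0)

    def test_all_events_reach_zero_all_censored_stay_one(self):
        assert km_estimate([1, 2, 3], [1, 1, 1]).survival[-1] == 0.0
        assert km_estimate([1, 2, 3], [0, 0, 0]).survival[-1] == 1.0

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(40, 100)
        e = rng.integers(0, 2, 100)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (np.diff(curve.at_risk) <= 0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 0])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(30, 60)
        e = np.ones(60, dtype=int)
        stat_vals = []
        for rep in range(20):
            g = rng.permutation(np.repeat([0, 1], 30))
            stat, p = logrank_test(np.concatenate([t, t]),
                                   np.concatenate([e, e]),
                                   np.concatenate([g, 1 - g]))
            stat_vals.append(stat)
        assert np.median(stat_vals) < 2.0

    def test_hand_worked_small_instance(self):
        """Two groups of three with all events: compare against an explicit
        observed-minus-expected accumulation over the risk sets."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=int)
        groups = np.array([0, 1, 0, 1, 0, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times):
            at_risk = times >= t
            d = int((times == t).sum())
            n = int(at_risk.sum())
            n1 = int((at_risk & (groups == 0)).sum())
            d1 = int(((times == t) & (groups == 0)).sum())
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        oracle = o_minus_e ** 2 / var
        stat, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(oracle, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_power_at_calibrated_mortality_gap(self, params):
        """The generator's class-specific hazards give the power predicted
        by the Schoenfeld approximation: Phi(sqrt(d p1 p2) |ln HR| - z)."""
        from scipy.stats import norm

        rejections = 0
        n_sims = 100
        for seed in range(n_sims):
            t = cohort.generate_cohort(params, seed=1000 + seed)
            stat, p = logrank_test(t.survival_time_days, t.death_indicator,
                                   t.true_class)
            rejections += p < 0.05
        lam1, lam2 = params.survival_hazards
        d = 166 * (0.5 * 0.728 + 0.5 * 0.482)  # expected events
        p1p2 = (81 * 85) / 166 ** 2
        power = norm.cdf(np.sqrt(d * p1p2) * abs(np.log(lam2 / lam1))
                         - norm.ppf(0.975))
        mc_sd = np.sqrt(power * (1 - power) / n_sims)
        # 3 MC sds plus slack for the approximation itself
        assert rejections / n_sims > power - 3 * mc_sd - 0.05


class TestCox:
    def test_identical_event_patterns_give_unit_hazard(self):
        t = np.tile([3.0, 5.0, 8.0, 13.0, 21.0], 2)
        e = np.tile([1, 1, 0, 1, 1], 2)
        g = np.repeat([0, 1], 5)
        hr = proportional_hazards(t, e, g)
        assert hr.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert hr.ci_lower < 1.0 < hr.ci_upper

    def test_three_subject_grid_search_oracle(self):
        """No ties: the partial likelihood is explicit; compare the Cox MLE
        with a dense grid maximization."""
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        groups = np.array([1, 0, 1])
        x = groups.astype(float)

        def pl(beta):
            ll = 0.0
            for i in np.argsort(times):
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return ll

        grid = np.linspace(-5, 5, 20001)
        beta_grid = grid[np.argmax([pl(b) for b in grid])]
        hr = proportional_hazards(times, events, groups)
        assert np.log(hr.hazard_ratio) == pytest.approx(beta_grid, abs=5e-3)

    def test_reference_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(2)
        t = np.concatenate([rng.exponential(20, 40),
                            rng.exponential(40, 40)])
        e = np.ones(80, dtype=int)
        g = np.repeat([0, 1], 40)
        fwd = proportional_hazards(t, e, g, reference=0)
        rev = proportional_hazards(t, e, g, reference=1)
        assert fwd.hazard_ratio == pytest.approx(1 / rev.hazard_ratio,
                                                 rel=1e-6)
        assert fwd.ci_lower == pytest.approx(1 / rev.ci_upper, rel=1e-6)

    def test_group_without_events_signalled(self):
        with pytest.raises(ValueError, match="no events"):
            proportional_hazards([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])


class TestFreeDays:
    @pytest.mark.parametrize("alive,occupied,window,expected", [
        (False, 10, 28, 0),    # died in the window
        (True, 5, 28, 23),     # alive, hospitalized 5 of 28 days
        (True, 28, 28, 0),     # occupied the entire window
        (True, 0, 28, 28),
    ])
    def test_stated_rules(self, alive, occupied, window, expected):
        assert free_days(alive, occupied, window) == expected

    def test_occupancy_beyond_window_rejected(self):
        with pytest.raises(ValueError):
            free_days(True, 30, 28)

    @given(st.booleans(), st.integers(0, 28))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_always_within_window(self, alive, occupied):
        assert 0 <= free_days(alive, occupied, 28) <= 28


class TestEasix:
    def test_direct_evaluation(self):
        assert easix(1.0, 250.0, 50.0) == pytest.approx(5.0)

    def test_value_at_published_median_inputs(self):
        # medians of ratios differ from ratios of medians: this equals
        # neither printed cohort EASIX summary, by design
        assert easix(1.0, 318.0, 41.0) == pytest.approx(7.76, abs=0.005)

    def test_linear_in_creatinine(self):
        assert easix(3.0, 200.0, 40.0) == pytest.approx(3 * easix(1.0, 200.0,
                                                                  40.0))

    def test_zero_platelets_rejected(self):
        with pytest.raises(ValueError):
            easix(1.0, 200.0, 0.0)


class TestClassSummary:
    def test_published_mortality_proportions(self):
        lab = np.repeat([0, 1], [81, 85])
        died_90 = np.concatenate([np.repeat([1, 0], [59, 22]),
                                  np.repeat([1, 0], [41, 44])])
        died_28 = np.concatenate([np.repeat([1, 0], [48, 33]),
                                  np.repeat([1, 0], [25, 60])])
        df = pd.DataFrame({"mortality_90d": died_90,
                           "mortality_28d": died_28})
        summary = class_summary(df, lab)
        assert summary.loc["mortality_90d", "class1_value"] == pytest.approx(
            72.8, abs=0.05)
        assert summary.loc["mortality_90d", "class2_value"] == pytest.approx(
            48.2, abs=0.05)
        assert summary.loc["mortality_28d", "class1_value"] == pytest.approx(
            59.3, abs=0.05)
        assert summary.loc["mortality_28d", "class2_value"] == pytest.approx(
            29.4, abs=0.05)

    def test_permuted_labels_give_null_differences(self, cohort166, roster):
        rng = np.random.default_rng(3)
        lab = rng.permutation(np.repeat([0, 1], 83))
        summary = class_summary(cohort166, lab, variables=roster)
        assert np.abs(summary["smd"]).max() < 0.5
        assert np.abs(summary["smd"]).median() < 0.2

    def test_smd_signs_match_generator_for_top_variables(self, params,
                                                         cohort166, roster,
                                                         true_labels):
        summary = class_summary(cohort166, true_labels, variables=roster)
        by_name = {s.name: s for s in params.variable_specs}
        for name in ("wbc", "platelets", "temperature", "glucose",
                     "pf_ratio"):
            sign = np.sign(by_name[name].loc[0] - by_name[name].loc[1])
            assert np.sign(summary.loc[name, "smd"]) == sign

    def test_test_choice_matches_variable_type(self, cohort166, roster,
                                               true_labels):
        summary = class_summary(cohort166, true_labels, variables=roster)
        assert summary.loc["allogeneic", "test"] == "chi-square"
        assert summary.loc["wbc", "test"] == "wilcoxon"
        assert summary.loc["sodium", "test"] == "t-test"

    def test_empty_class_rejected(self, cohort166, roster):
        with pytest.raises(ValueError):
            class_summary(cohort166, np.zeros(len(cohort166)),
                          variables=roster)
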