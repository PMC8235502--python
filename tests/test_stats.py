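"""Survival statistics against brute-force oracles and lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest

from conftest import oracle_efron_loglik, oracle_km, oracle_logrank_z, oracle_spearman
from stilquant import stats
from stilquant.synthetic import CohortSpec, simulate_cohort


class TestBlockScores:
    @pytest.mark.parametrize(
        "scores,expected", [([20, 30], 25.0), ([15], 15.0), ([None, 8], 8.0)]
    )
    def test_average_of_available_blocks(self, scores, expected):
        assert stats.combine_block_scores(scores) == expected

    def test_empty_is_missing(self):
        assert np.isnan(stats.combine_block_scores([]))

    def test_three_blocks_rejected(self):
        with pytest.raises(ValueError):
            stats.combine_block_scores([1, 2, 3])


class TestDichotomize:
    def test_manual_boundary_10_is_low(self):
        d = stats.dichotomize([9.9, 10.0, 10.1], 10.0, "strictly_greater")
        assert d.high.tolist() == [False, False, True]
        assert d.rule == "strictly_greater"

    def test_density_boundary_470_is_high(self):
        d = stats.dichotomize([469.9, 470.0, 470.1], 470.0, "geq")
        assert d.high.tolist() == [False, True, True]

    def test_empty_input(self):
        assert stats.dichotomize([], 10.0, "geq").high.size == 0


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = stats.km_estimate([5, 10, 15], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_three_events_no_ties(self):
        km = stats.km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_tied_events_match_risk_set_oracle(self):
        times = [2, 2, 3, 3, 3, 5, 7, 7, 9, 11]
        events = [1, 1, 1, 0, 1, 0, 1, 1, 0, 1]
        km = stats.km_estimate(times, events)
        t_o, s_o = oracle_km(times, events)
        for t, s in zip(t_o, s_o):
            assert km.survival_at(t) == pytest.approx(s)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 50))
            times = rng.integers(1, 20, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            km = stats.km_estimate(times, events)
            t_o, s_o = oracle_km(times, events)
            for t, s in zip(t_o, s_o):
                assert km.survival_at(t) == pytest.approx(s)

    def test_ci_contains_estimate(self):
        km = stats.km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert np.all(km.ci_low <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_high + 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        lr = stats.logrank_stat(times, events, groups)
        assert lr.z == pytest.approx(0.0, abs=1e-12)
        assert lr.p == pytest.approx(1.0)

    def test_small_fixture_matches_summation_oracle(self):
        times = [3, 5, 7, 2, 8, 1, 4, 6]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        lr = stats.logrank_stat(times, events, groups)
        assert lr.z == pytest.approx(oracle_logrank_z(times, events, groups), abs=1e-12)

    def test_label_swap_flips_sign(self):
        times = [3, 5, 7, 2, 8, 1, 4, 6]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        a = stats.logrank_stat(times, events, g)
        b = stats.logrank_stat(times, events, ~g)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_matches_lifelines_chi2(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60).astype(bool)
        lr = stats.logrank_stat(times, events, g)
        ll = logrank_test(times[g], times[~g], events[g], events[~g])
        assert lr.chi2 == pytest.approx(ll.test_statistic, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.logrank_stat([1, 2], [1, 1], [True, True])


class TestCox:
    def test_constant_zero_covariate_hr_one(self):
        df = pd.DataFrame(
            {"t": [1, 2, 3, 4, 5, 6], "e": [1, 0, 1, 1, 0, 1], "z": 0.0}
        )
        fit = stats.cox_fit(df, "t", "e", ["z"])
        assert fit.hr("z") == 1.0
        assert fit.terms.loc["z", "p"] == 1.0

    def test_binary_covariate_matches_partial_likelihood_grid(self):
        # 12-subject fixture with ties; oracle = dense grid over the Efron
        # partial likelihood
        times = np.array([2, 3, 3, 5, 6, 7, 8, 8, 9, 11, 12, 14], float)
        events = np.array([1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 0, 1])
        x = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0], float)
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        fit = stats.cox_fit(df, "t", "e", ["x"])
        grid = np.linspace(-3, 3, 120001)
        lls = [oracle_efron_loglik(b, times, events, x) for b in grid]
        beta_hat = grid[int(np.argmax(lls))]
        assert fit.terms.loc["x", "coef"] == pytest.approx(beta_hat, abs=1e-4)

    def test_scaling_renames_term_and_scales_hr(self):
        df = simulate_cohort(CohortSpec(seed=8, n=400))
        fit = stats.cox_fit(df, "os_time", "os_event", ["stil_density"], {"stil_density": 300})
        raw = stats.cox_fit(df, "os_time", "os_event", ["stil_density"])
        assert "stil_density_per_300" in fit.terms.index
        assert fit.terms.loc["stil_density_per_300", "coef"] == pytest.approx(
            raw.terms.loc["stil_density", "coef"] * 300, rel=1e-6
        )

    def test_complete_cases_only(self):
        df = pd.DataFrame(
            {
                "t": [1, 2, 3, 4, 5, 6, 7, 8],
                "e": [1, 0, 1, 1, 0, 1, 1, 0],
                "x": [0.5, np.nan, 0.2, 0.9, 0.1, np.nan, 0.4, 0.3],
            }
        )
        fit = stats.cox_fit(df, "t", "e", ["x"])
        assert fit.n_used == 6

    def test_no_events_rejected(self):
        df = pd.DataFrame({"t": [1, 2, 3], "e": [0, 0, 0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(stats.CoxConvergenceError):
            stats.cox_fit(df, "t", "e", ["x"])

    def test_monotone_likelihood_explicit_error(self):
        # perfect separation: the covariate orders the event times exactly
        df = pd.DataFrame(
            {"t": [1, 2, 3, 4, 5, 6], "e": 1, "x": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]}
        )
        with pytest.raises(stats.CoxConvergenceError):
            stats.cox_fit(df, "t", "e", ["x"])

    def test_ci_contains_point_estimate(self):
        df = simulate_cohort(CohortSpec(seed=13, n=300))
        df = stats.prepare_cohort(df)
        fit = stats.cox_fit(
            df, "os_time", "os_event", ["stil_density"] + stats.COVARIATE_CODINGS,
            {"stil_density": 300},
        )
        assert np.all(fit.terms["ci_low"] <= fit.terms["hr"])
        assert np.all(fit.terms["hr"] <= fit.terms["ci_high"])
        assert np.all((fit.terms["p"] >= 0) & (fit.terms["p"] <= 1))


class TestMaxstat:
    def test_two_distinct_values_reduces_to_logrank(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 1, 0, 1, 1, 0, 1]
        biomarker = np.array([100.0, 100, 100, 100, 900, 900, 900, 900])
        cut = stats.maxstat_cutpoint(times, events, biomarker, window=(0.05, 0.95))
        lr = stats.logrank_stat(times, events, biomarker >= 900)
        assert cut.cutpoint == 900.0
        assert cut.statistic == pytest.approx(abs(lr.z))
        assert cut.n_candidates == 1

    def test_cutpoint_inside_window(self, rng):
        df = simulate_cohort(CohortSpec(seed=21))
        cut = stats.maxstat_cutpoint(df.os_time, df.os_event, df.stil_density)
        lo, hi = np.quantile(df.stil_density, [0.10, 0.90])
        assert lo < cut.cutpoint <= hi
        assert 0 <= cut.p_adjusted <= 1
        assert np.isfinite(cut.statistic)

    def test_constant_biomarker_rejected(self):
        with pytest.raises(ValueError):
            stats.maxstat_cutpoint([1, 2, 3, 4], [1, 1, 0, 1], [5.0, 5.0, 5.0, 5.0])

    def test_permutation_p_agrees_in_order_with_bound(self):
        spec = CohortSpec(seed=5, n=120, effect="step", cov_log_hrs={})
        df = simulate_cohort(spec)
        a = stats.maxstat_cutpoint(df.os_time, df.os_event, df.stil_density)
        b = stats.maxstat_cutpoint(
            df.os_time, df.os_event, df.stil_density,
            p_method="permutation", n_permutations=200, seed=1,
        )
        assert a.cutpoint == b.cutpoint
        # the closed-form bound and the Monte-Carlo null agree to first order
        assert abs(a.p_adjusted - b.p_adjusted) < 0.10


class TestSpearman:
    def test_identical_and_reversed(self):
        m = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], float)
        rho, p = stats.pairwise_spearman(m)
        assert rho.iloc[0, 1] == pytest.approx(1.0)
        assert rho.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho.values, rho.values.T)

    def test_tied_data_matches_exhaustive_rank_oracle(self):
        a = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8], float)
        b = np.array([2, 7, 1, 8, 2, 8, 1, 8, 2, 8, 4, 5], float)
        rho, _ = stats.pairwise_spearman(np.vstack([a, b]))
        assert rho.iloc[0, 1] == pytest.approx(oracle_spearman(a, b), abs=1e-12)

    def test_constant_vector_missing(self):
        m = np.array([[1, 1, 1, 1], [1, 2, 3, 4]], float)
        rho, p = stats.pairwise_spearman(m)
        assert np.isnan(rho.iloc[0, 1])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            stats.pairwise_spearman(np.array([[1, 2], [3, 4]], float))


class TestConcordance:
    def test_constructed_2x2_matches_printed_rates(self):
        # TP=121, FN=28, TN=91, FP=22 → sensitivity 0.812, specificity 0.805
        manual = np.array([True] * 149 + [False] * 113)
        auto = np.array([True] * 121 + [False] * 28 + [False] * 91 + [True] * 22)
        rep = stats.concordance_report(manual, auto)
        assert rep.tp == 121 and rep.fn == 28 and rep.tn == 91 and rep.fp == 22
        assert round(rep.sensitivity, 3) == 0.812
        assert round(rep.specificity, 3) == 0.805
        assert len(rep.discrepant) == 50

    def test_perfect_agreement(self):
        g = np.array([True, False, True, False])
        rep = stats.concordance_report(g, g)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.discrepant.empty

    def test_all_negative_manual_sensitivity_missing(self):
        rep = stats.concordance_report([False, False], [False, True])
        assert np.isnan(rep.sensitivity)

    def test_near_cutpoint_flags(self):
        rep = stats.concordance_report(
            [True, True], [False, False],
            ids=["a", "b"],
            manual_scores=[12.0, 60.0], auto_scores=[400.0, 90.0],
            manual_cutpoint=10.0, auto_cutpoint=470.0,
            manual_band=10.0, auto_band=250.0,
        )
        flags = dict(zip(rep.discrepant["id"], rep.discrepant["near_cutpoints"]))
        assert flags == {"a": True, "b": False}

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            stats.concordance_report([True], [True, False])


class TestPrepareCohort:
    def test_derives_codings(self):
        df = simulate_cohort(CohortSpec(seed=1, n=50))
        out = stats.prepare_cohort(df)
        assert set(stats.COVARIATE_CODINGS) <= set(out.columns)
        assert np.array_equal(out["age_ge50"], (df["age_years"] >= 50).astype(float))
        assert np.array_equal(
            out["nodes_ge4"], (df["n_positive_nodes"] >= 4).astype(float)
        )

    def test_all_schema_violations_reported_together(self):
        df = simulate_cohort(CohortSpec(seed=1, n=10))
        df.loc[0, "os_time"] = -5.0
        df.loc[1, "os_event"] = 2
        df.loc[2, "tumor_type"] = "mystery"
        with pytest.raises(ValueError) as err:
            stats.prepare_cohort(df)
        msg = str(err.value)
        assert "negative times" in msg and "non-binary" in msg and "mystery" in msg
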