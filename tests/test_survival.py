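"""Kaplan-Meier / log-rank engine and prognostic profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbpscape.datatypes import SurvivalCohort, ValidationError
from rbpscape import survival as surv
from rbpscape.synth import generate_survival_cohort


class TestDichotomize:
    def test_even_split(self):
        high, low = surv.dichotomize_by_median(
            pd.Series({"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0}))
        assert set(high) == {"p3", "p4"} and set(low) == {"p1", "p2"}

    def test_ties_go_low(self):
        high, low = surv.dichotomize_by_median(
            pd.Series({"p1": 1.0, "p2": 2.0, "p3": 2.0, "p4": 3.0}))
        assert set(high) == {"p4"} and set(low) == {"p1", "p2", "p3"}

    def test_partition_is_complete(self, rng):
        s = pd.Series(rng.normal(0, 1, 31), index=[f"p{i}" for i in range(31)])
        high, low = surv.dichotomize_by_median(s)
        assert len(high) + len(low) == 31
        assert len(set(high) & set(low)) == 0

    def test_constant_values_raise(self):
        with pytest.raises(ValidationError):
            surv.dichotomize_by_median(pd.Series([2.0] * 6))


class TestKMCurve:
    def test_no_censoring_equals_empirical(self):
        c = surv.km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        c = surv.km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert c.event_times.size == 0

    def test_hand_computed_mixed_fixture(self):
        # 6 patients: times 1,2+,3,3,4+,5 (+ = censored)
        # t=1: 6 at risk, 1 event -> 5/6
        # t=3: 4 at risk, 2 events -> 5/6 * 2/4 = 5/12
        # t=5: 1 at risk, 1 event -> 0
        c = surv.km_curve([1, 2, 3, 3, 4, 5], [1, 0, 1, 1, 0, 1])
        np.testing.assert_allclose(c.event_times, [1, 3, 5])
        np.testing.assert_allclose(c.survival, [5 / 6, 5 / 12, 0.0])
        np.testing.assert_allclose(c.at_risk, [6, 4, 1])

    def test_censored_at_event_time_counts_at_risk(self):
        # censoring at t=2 ties the event at t=2: both in the risk set
        c = surv.km_curve([1.0, 2.0, 2.0], [1, 0, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3])
        np.testing.assert_allclose(c.at_risk, [3, 2])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=40))
    def test_km_equals_empirical_without_censoring(self, times):
        t = np.asarray(times)
        c = surv.km_curve(t, np.ones(len(t), int))
        for u, s in zip(c.event_times, c.survival):
            assert s == pytest.approx(np.mean(t > u))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(5, 80) + 0.01
        e = rng.integers(0, 2, 80)
        if e.sum() == 0:
            e[0] = 1
        c = surv.km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u, s in zip(c.event_times, c.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]))


class TestLogRank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = surv.logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.extra["hazard_ratio_oe"] == pytest.approx(1.0)

    def test_relabel_inverts_hazard_ratio(self, rng):
        ta, tb = rng.exponential(2, 50), rng.exponential(5, 60)
        ea = np.ones(50, int); eb = np.ones(60, int)
        ab = surv.logrank_test(ta, ea, tb, eb)
        ba = surv.logrank_test(tb, eb, ta, ea)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.extra["hazard_ratio_oe"] == pytest.approx(
            1.0 / ba.extra["hazard_ratio_oe"])

    def test_matches_lifelines_statistic(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        ta, tb = rng.exponential(2, 60), rng.exponential(4, 70)
        ea = (rng.random(60) < 0.8).astype(int)
        eb = (rng.random(70) < 0.8).astype(int)
        res = surv.logrank_test(ta, ea, tb, eb)
        ll = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_zero_events_raise(self):
        with pytest.raises(ValidationError):
            surv.logrank_test([1.0], [0], [2.0], [0])


class TestGenerator:
    def test_no_censoring_all_events(self):
        c = generate_survival_cohort(50, {"g": 1.0}, 0.0, seed=1)
        assert (c.data["event"] == 1).all()

    def test_deterministic(self):
        a = generate_survival_cohort(30, {"g": 2.0}, 0.3, seed=5)
        b = generate_survival_cohort(30, {"g": 2.0}, 0.3, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_invalid_hazard_raises(self):
        with pytest.raises(ValidationError):
            generate_survival_cohort(10, {"g": 0.0}, 0.0, seed=1)

    def test_planted_hazard_detected(self):
        c = generate_survival_cohort(300, {"g": 3.0}, 0.2, seed=2)
        prof, _ = surv.prognostic_profiles(c)
        assert prof.loc["g", "neg_log_p"] > 3.0

    def test_latent_factor_cohort_recovers_planted_ratios(self):
        """Shared-frailty cohort: median-split HR tracks each gene's target
        even with many genes carrying effects simultaneously."""
        from rbpscape.synth import generate_correlated_survival_cohort
        effects = {f"null{i}": 1.0 for i in range(20)}
        effects.update({f"hit{i}": 3.0 for i in range(5)})
        hits = [g for g in effects if g.startswith("hit")]
        nulls = [g for g in effects if g.startswith("null")]
        hrs = {g: [] for g in effects}
        for seed in range(8):
            c = generate_correlated_survival_cohort(400, effects, 0.2,
                                                    seed=seed)
            prof, _ = surv.prognostic_profiles(c)
            for g in effects:
                hrs[g].append(prof.loc[g, "hazard_ratio_oe"])
        med = {g: np.median(v) for g, v in hrs.items()}
        assert all(1.8 < med[g] < 4.5 for g in hits)
        assert all(0.6 < med[g] < 1.6 for g in nulls)


class TestPrognosticProfiles:
    def test_identical_expression_identical_profiles(self, rng):
        n = 60
        expr_row = rng.lognormal(1, 1, n)
        expr = pd.DataFrame([expr_row, expr_row], index=["gA", "gB"],
                            columns=[f"p{i}" for i in range(n)])
        data = pd.DataFrame({"time": rng.exponential(5, n) + 0.01,
                             "event": rng.integers(0, 2, n)},
                            index=expr.columns)
        data.iloc[0, 1] = 1
        cohort = SurvivalCohort(data=data, expression=expr)
        prof, _ = surv.prognostic_profiles(cohort)
        assert prof.loc["gA"].equals(prof.loc["gB"])

    def test_unsplittable_gene_excluded(self, rng):
        n = 20
        expr = pd.DataFrame([np.ones(n), rng.lognormal(0, 1, n)],
                            index=["flat", "ok"],
                            columns=[f"p{i}" for i in range(n)])
        data = pd.DataFrame({"time": rng.exponential(5, n) + 0.01,
                             "event": np.ones(n, int)}, index=expr.columns)
        cohort = SurvivalCohort(data=data, expression=expr)
        prof, excluded = surv.prognostic_profiles(cohort)
        assert excluded == ["flat"] and "ok" in prof.index


class TestPathSurvivalReport:
    def _inputs(self, rho_sign, rng, n=15):
        genes = [f"g{i:02d}" for i in range(n)]
        path = pd.Series(np.arange(n, dtype=float), index=genes)
        neg_log_p = pd.Series(
            np.arange(n, dtype=float)[::rho_sign] + rng.normal(0, 0.01, n),
            index=genes)
        profiles = pd.DataFrame({
            "neg_log_p": neg_log_p,
            "hazard_ratio_oe": np.ones(n)}, index=genes)
        selection = {"shortest": genes[:5], "intermediate": genes[5:10],
                     "longest": genes[10:]}
        return selection, path, profiles

    def test_planted_trend_recovered(self, rng):
        selection, path, profiles = self._inputs(1, rng)
        report, corrs = surv.path_length_survival_report(selection, path,
                                                         profiles)
        assert corrs["all"].statistic > 0.9
        assert list(report.columns)[:2] == ["group", "gene"]

    def test_single_gene_selection_flagged_degenerate(self, rng):
        _sel, path, profiles = self._inputs(1, rng)
        report, corrs = surv.path_length_survival_report(
            {"shortest": ["g00"]}, path, profiles)
        assert corrs["shortest"].extra["degenerate"]

    def test_missing_profile_flagged(self, rng):
        selection, path, profiles = self._inputs(1, rng)
        report, _ = surv.path_length_survival_report(
            {"shortest": ["g00", "missing"]}, path,
            profiles.drop(index=["g01"]))
        assert report.loc[report["gene"] == "missing", "flagged"].all()


class TestPrognosisComparison:
    def test_identical_partitions_high_p(self, rng):
        nlp = pd.Series(rng.exponential(1, 200),
                        index=[f"g{i}" for i in range(200)])
        partition = pd.Series(np.tile(["a", "b"], 100), index=nlp.index)
        # a and b are random halves of the same distribution
        res = surv.compare_prognosis_distributions(nlp, partition)
        assert len(res) == 1 and res[0].p_value > 0.05

    def test_planted_difference_detected(self, rng):
        nlp = pd.Series(np.concatenate([rng.exponential(0.5, 150),
                                        rng.exponential(3.0, 150)]),
                        index=[f"g{i}" for i in range(300)])
        partition = pd.Series(["high_var"] * 150 + ["low_var"] * 150,
                              index=nlp.index)
        res = surv.compare_prognosis_distributions(nlp, partition)
        assert res[0].p_value < 0.01
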