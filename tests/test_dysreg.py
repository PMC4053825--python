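"""Fold-change summaries, SUR calling, enrichment and variability classes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_summary
from rbpscape.datatypes import ExpressionMatrix, ValidationError
from rbpscape import dysreg
from rbpscape.dysreg import (classify_sur, classify_variability,
                             cluster_cancers, hypergeometric_enrichment,
                             linkage_to_newick, patient_fold_changes,
                             summarize_fold_changes, tumor_matched_tests,
                             upper_quartile_flags)
from rbpscape.synth import CANCER_TISSUE


def _tumor(values, genes=("gA",)):
    df = pd.DataFrame(values, index=list(genes),
                      columns=[f"p{i}_T" for i in range(len(values[0]))])
    meta = pd.DataFrame({"context": "c", "kind": "tumor",
                         "patient_id": [f"p{i}" for i in range(df.shape[1])]},
                        index=df.columns)
    return ExpressionMatrix(values=df.astype(float), samples=meta)


class TestPatientFoldChanges:
    def test_plain_ratio(self):
        t = _tumor([[18.0, 20.0, 22.0]])
        r = patient_fold_changes(t, pd.Series({"gA": 2.0}), pseudocount=0.0)
        np.testing.assert_allclose(r.loc["gA"], [9.0, 10.0, 11.0])

    def test_pseudocount_guards_zero_reference(self):
        t = _tumor([[5.0]])
        r = patient_fold_changes(t, pd.Series({"gA": 0.0}), pseudocount=0.01)
        assert r.iloc[0, 0] == pytest.approx(5.01 / 0.01)

    def test_identity_when_tumor_equals_healthy(self):
        t = _tumor([[3.0, 3.0]])
        r = patient_fold_changes(t, pd.Series({"gA": 3.0}), pseudocount=0.01)
        np.testing.assert_allclose(r.loc["gA"], 1.0)

    def test_zero_reference_without_pseudocount_raises(self):
        t = _tumor([[5.0]])
        with pytest.raises(ValidationError):
            patient_fold_changes(t, pd.Series({"gA": 0.0}), pseudocount=0.0)

    def test_missing_reference_raises(self):
        t = _tumor([[5.0]])
        with pytest.raises(ValidationError):
            patient_fold_changes(t, pd.Series({"gB": 1.0}))


class TestSummaries:
    def test_median_log2_mad(self):
        r = pd.DataFrame([[9.0, 10.0, 11.0]], index=["gA"],
                         columns=["p0", "p1", "p2"])
        s = summarize_fold_changes({"c0": r})
        assert s.median_ratio.loc["gA", "c0"] == 10.0
        assert s.log2_median_ratio.loc["gA", "c0"] == pytest.approx(np.log2(10))
        assert s.mad_ratio.loc["gA", "c0"] == 1.0

    def test_mad_robust_to_outlier(self):
        r = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 100.0]], index=["gA"],
                         columns=[f"p{i}" for i in range(5)])
        s = summarize_fold_changes({"c0": r})
        assert s.median_ratio.loc["gA", "c0"] == 3.0
        assert s.mad_ratio.loc["gA", "c0"] == 1.0

    def test_single_patient_mad_zero(self):
        r = pd.DataFrame([[7.0]], index=["gA"], columns=["p0"])
        s = summarize_fold_changes({"c0": r})
        assert s.mad_ratio.loc["gA", "c0"] == 0.0


class TestClassifySur:
    def _summary(self, medians_per_gene):
        cancers = [f"c{i}" for i in range(len(next(iter(medians_per_gene.values()))))]
        med = pd.DataFrame(medians_per_gene, index=cancers).T
        med.columns = cancers
        return make_summary(med)

    def test_six_of_nine_is_sur(self):
        s = self._summary({"gA": [10.0] * 6 + [1.0] * 3})
        assert classify_sur(s).table.loc["gA", "is_sur"]

    def test_five_of_nine_is_not_sur(self):
        s = self._summary({"gA": [10.0] * 5 + [1.0] * 4})
        assert not classify_sur(s).table.loc["gA", "is_sur"]

    def test_threshold_is_inclusive(self):
        s = self._summary({"gA": [9.0] * 6 + [1.0] * 3})
        assert classify_sur(s).table.loc["gA", "is_sur"]

    def test_monotone_in_both_thresholds(self, rng):
        med = pd.DataFrame(rng.uniform(0.5, 20, (60, 9)),
                           index=[f"g{i}" for i in range(60)],
                           columns=[f"c{i}" for i in range(9)])
        s = make_summary(med)
        base = classify_sur(s, 9.0, 6).sur_genes
        assert classify_sur(s, 12.0, 6).sur_genes <= base
        assert classify_sur(s, 9.0, 7).sur_genes <= base

    def test_log2_scale_option(self):
        s = self._summary({"gA": [10.0] * 9})
        call = classify_sur(s, ratio_threshold=np.log2(9.0), scale="log2")
        assert call.table.loc["gA", "is_sur"]

    def test_too_few_cancers_raises(self):
        s = self._summary({"gA": [10.0] * 4})
        with pytest.raises(ValidationError):
            classify_sur(s, min_cancers=6)


class TestUpperQuartile:
    def test_percentile_cut(self):
        med = pd.DataFrame({"c0": np.arange(1.0, 101.0)},
                           index=[f"g{i:03d}" for i in range(100)])
        flags = upper_quartile_flags(make_summary(med))
        assert flags.sum() == 25
        assert flags.loc["g099"] and not flags.loc["g000"]

    def test_all_equal_flags_all(self):
        med = pd.DataFrame({"c0": np.ones(8)}, index=[f"g{i}" for i in range(8)])
        assert upper_quartile_flags(make_summary(med)).all()


class TestHypergeometric:
    def test_upper_tail_from_zero_is_one(self):
        assert hypergeometric_enrichment(0, 5, 3, 20).p_value == 1.0

    def test_all_successes_drawn_exact(self):
        # k = n = K: only C(N-n, K-n)/... term; evaluate directly
        from math import comb
        N, n = 10, 4
        want = comb(n, n) * comb(N - n, 0) / comb(N, n)
        assert hypergeometric_enrichment(n, n, n, N).p_value == pytest.approx(want)

    def test_matches_enumeration_oracle(self):
        # N=12, n=5, K=6: brute force over all C(12,6) draws
        N, n, K = 12, 5, 6
        marked = set(range(n))
        draws = list(itertools.combinations(range(N), K))
        for k in range(0, min(K, n) + 1):
            want = sum(1 for d in draws if len(marked.intersection(d)) >= k) / len(draws)
            assert hypergeometric_enrichment(k, K, n, N).p_value == pytest.approx(want)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(6, 5, 10, 20)


class TestTumorMatched:
    def _cohort(self, t_vals, n_vals, gene="gA", cancer="c0"):
        pats = [f"p{i}" for i in range(len(t_vals))]
        tv = pd.DataFrame([t_vals], index=[gene],
                          columns=[f"{p}_T" for p in pats]).astype(float)
        tm = pd.DataFrame({"context": cancer, "kind": "tumor",
                           "patient_id": pats}, index=tv.columns)
        nv = pd.DataFrame([n_vals], index=[gene],
                          columns=[f"{p}_N" for p in pats]).astype(float)
        nm = pd.DataFrame({"context": cancer, "kind": "matched_normal",
                           "patient_id": pats}, index=nv.columns)
        return {cancer: (ExpressionMatrix(values=tv, samples=tm),
                         ExpressionMatrix(values=nv, samples=nm))}

    def test_equal_pairs_give_p_one(self):
        p, counts = tumor_matched_tests(self._cohort([4.0] * 6, [4.0] * 6))
        assert p.loc["gA", "c0"] == 1.0
        assert counts.loc["gA"] == 0

    def test_planted_shift_detected(self, rng):
        base = rng.lognormal(2, 0.3, 50)
        noise = rng.lognormal(0, 0.5 * np.log(2), 50)
        p, counts = tumor_matched_tests(
            self._cohort((base * 4 * noise).tolist(), base.tolist()))
        assert p.loc["gA", "c0"] < 0.001
        assert counts.loc["gA"] == 1

    def test_missing_normal_is_untestable(self):
        cohort = self._cohort([1.0] * 4, [1.0] * 4)
        cohort["c1"] = (cohort["c0"][0], None)
        p, counts = tumor_matched_tests(cohort)
        assert np.isnan(p.loc["gA", "c1"])

    def test_null_type1_near_nominal(self, rng):
        """Paired-t rejection at 0.05 close to nominal on null pairs."""
        rej = 0
        reps = 400
        for _ in range(reps):
            diffs = rng.normal(0, 1, 10)
            rej += dysreg._paired_t_p(diffs) < 0.05
        assert 0.02 < rej / reps < 0.09


class TestVariability:
    def test_quartile_partition(self):
        mad = pd.DataFrame({"c0": np.arange(1.0, 101.0)},
                           index=[f"g{i:03d}" for i in range(100)])
        med = mad.copy()
        vc = classify_variability(make_summary(med, mad), "c0")
        counts = vc.label.value_counts()
        assert abs(counts["low"] - 25) <= 1
        assert abs(counts["high"] - 25) <= 1
        assert abs(counts["medium"] - 50) <= 2

    def test_all_equal_is_all_medium(self):
        mad = pd.DataFrame({"c0": np.ones(10)}, index=[f"g{i}" for i in range(10)])
        vc = classify_variability(make_summary(mad, mad), "c0")
        assert (vc.label == "medium").all()

    def test_two_component_mixture_recovered(self, rng):
        low = rng.uniform(0.01, 0.1, 50)
        high = rng.uniform(10, 20, 50)
        mad = pd.DataFrame({"c0": np.concatenate([low, high])},
                           index=[f"g{i:03d}" for i in range(100)])
        vc = classify_variability(make_summary(mad, mad), "c0")
        assert (vc.label.iloc[:25] == "low").all() or (
            vc.label.iloc[:50].isin(["low", "medium"])).all()
        assert (vc.label.iloc[75:] == "high").all() or (
            vc.label.iloc[50:].isin(["medium", "high"])).all()


class TestClusterCancers:
    def test_identical_columns_merge_first_at_zero(self, rng):
        x = rng.normal(0, 1, 30)
        m = pd.DataFrame({"a": x, "b": x, "c": rng.normal(0, 1, 30)})
        z, labels = cluster_cancers(m)
        assert {int(z[0, 0]), int(z[0, 1])} == {labels.index("a"), labels.index("b")}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_shared_profile_pair_merges_first(self, small_dataset):
        from rbpscape.dysreg import patient_fold_changes, summarize_fold_changes
        d = small_dataset
        ratios = {c: patient_fold_changes(t, d.healthy.values[CANCER_TISSUE[c]])
                  for c, (t, _n) in d.cohorts.items()}
        s = summarize_fold_changes(ratios)
        # plant two cancers with a duplicated dysregulation profile
        m = s.log2_median_ratio.copy()
        m["lung_sq"] = m["lung_ad"] + 0.01 * np.arange(len(m))
        z, labels = cluster_cancers(m)
        first = {int(z[0, 0]), int(z[0, 1])}
        assert first == {labels.index("lung_ad"), labels.index("lung_sq")}

    def test_column_permutation_invariant_topology(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (40, 5)),
                         columns=list("abcde"))
        def merge_sets(frame):
            z, labels = cluster_cancers(frame)
            n = len(labels)
            members = {i: frozenset([labels[i]]) for i in range(n)}
            out = []
            for j, (a, b, _h, _c) in enumerate(z):
                s = members[int(a)] | members[int(b)]
                members[n + j] = s
                out.append(s)
            return out
        assert merge_sets(m) == merge_sets(m[list("ecabd")])

    def test_zero_variance_column_raises(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="b"):
            cluster_cancers(m)

    def test_newick_rendering(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.1, 2.9],
                          "c": [3.0, 1.0, -2.0]})
        z, labels = cluster_cancers(m)
        nwk = linkage_to_newick(z, labels)
        assert nwk.endswith(";") and all(l in nwk for l in labels)
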