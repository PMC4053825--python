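"""Stage 5 — in-house Kaplan-Meier / log-rank survival engine.

For each gene, patients are split at the median expression (ties to the low
group), the two groups are compared with the log-rank test, and the
prognostic impact is summarized as -log10 of the log-rank p-value together
with an observed/expected hazard-ratio estimate.  Profiles are then related
to network path lengths and compared across dysregulation and variability
classes with two-sample KS tests.

The product-limit estimator and the log-rank test are implemented here
directly from their defining formulas: patients censored exactly at an
event time count as at risk at that time, the log-rank statistic is the
usual chi-square with one degree of freedom, and the hazard ratio is
(O_a/E_a)/(O_b/E_b) from the same bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import KMCurve, SurvivalCohort, TestResult, ValidationError

#: floor applied to p-values before the -log10 transform
P_FLOOR = float(np.finfo(float).tiny)


def dichotomize_by_median(expression: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split patients into high/low expression halves at the median.

    Patients exactly at the median go to the low group, so
    |high| <= |low| <= |high| + (count at median).  All-identical values
    admit no split and raise.
    """
    values = expression.astype(float)
    if len(values) < 4:
        raise ValidationError("median split needs >= 4 patients")
    med = float(values.median())
    high = values.index[values > med]
    low = values.index[values <= med]
    if len(high) == 0:
        raise ValidationError("no split possible: all values at or below median")
    return high, low


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are positive follow-up times; ``events`` are 1 for an
    observed event, 0 for censoring.  Estimates are reported at the
    distinct event times; patients censored at an event time are counted
    at risk there.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValidationError("empty cohort")
    if (t <= 0).any():
        raise ValidationError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in event_times],
                        dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times=event_times, survival=survival,
                   at_risk=at_risk, n_events=n_events)


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test with an observed/expected hazard ratio.

    Chi-square statistic with 1 df; ``extra['hazard_ratio_oe']`` is
    (O_a/E_a)/(O_b/E_b).  At least one event across the two groups is
    required.
    """
    ta = np.asarray(times_a, float)
    ea = np.asarray(events_a, int)
    tb = np.asarray(times_b, float)
    eb = np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test requires >= 1 event")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones_like(ta, bool), np.zeros_like(tb, bool)])
    event_times = np.unique(t[e == 1])
    o_a = e_a = var = 0.0
    d_a_total = float(ea.sum())
    d_b_total = float(eb.sum())
    for u in event_times:
        at_risk = t >= u
        n = float(at_risk.sum())
        n_a = float((at_risk & grp_a).sum())
        d = float(((t == u) & (e == 1)).sum())
        d_a = float(((t == u) & (e == 1) & grp_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    e_b = (d_a_total + d_b_total) - e_a
    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = (o_a - e_a) ** 2 / var
        p = float(sps.chi2.sf(stat, df=1))
    if e_a > 0 and e_b > 0 and d_b_total > 0:
        hr = (o_a / e_a) / (d_b_total / e_b)
    else:
        hr = np.nan
    return TestResult(method="logrank", statistic=float(stat),
                      p_value=min(p, 1.0),
                      n_per_group=(ta.size, tb.size),
                      extra={"hazard_ratio_oe": float(hr),
                             "observed_a": o_a, "expected_a": e_a,
                             "observed_b": d_b_total, "expected_b": e_b})


def prognostic_profiles(cohort: SurvivalCohort,
                        genes=None) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene prognostic impact: median split then log-rank.

    Returns ``(profiles, excluded)`` where ``profiles`` has one row per
    testable gene (logrank_p, neg_log_p, hazard_ratio_oe, n_high, n_low)
    and ``excluded`` lists genes whose expression admitted no median split.
    """
    if genes is None:
        genes = list(cohort.expression.index)
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        raise ValidationError(f"cohort lacks expression for: {missing[:5]}")
    times = cohort.data["time"]
    events = cohort.data["event"]
    rows, excluded = {}, []
    for g in genes:
        expr = cohort.expression.loc[g]
        try:
            high, low = dichotomize_by_median(expr)
        except ValidationError:
            excluded.append(g)
            continue
        res = logrank_test(times.loc[high], events.loc[high],
                           times.loc[low], events.loc[low])
        p = max(res.p_value, P_FLOOR)
        rows[g] = {"logrank_p": p, "neg_log_p": -np.log10(p),
                   "hazard_ratio_oe": res.extra["hazard_ratio_oe"],
                   "n_high": len(high), "n_low": len(low)}
    profiles = pd.DataFrame.from_dict(rows, orient="index")
    profiles.index.name = "gene"
    return profiles, excluded


def path_length_survival_report(selection: dict[str, list[str]],
                                path_lengths: pd.Series,
                                profiles: pd.DataFrame
                                ) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Pair each selected gene's mean path length with its prognostic impact.

    ``selection`` maps group name (shortest/intermediate/longest) to gene
    lists; rows are sorted by mean path length within each group.  Genes
    without a profile are kept but flagged.  A Spearman rank correlation of
    path length vs -log10 p is computed per group and over all selected
    genes; undefined correlations (fewer than three complete rows, or a
    constant vector) are flagged degenerate.
    """
    rows = []
    for group, genes in selection.items():
        for g in genes:
            has_profile = g in profiles.index
            rows.append({
                "group": group, "gene": g,
                "mean_path": float(path_lengths.get(g, np.nan)),
                "neg_log_p": float(profiles.loc[g, "neg_log_p"]) if has_profile else np.nan,
                "hazard_ratio_oe": float(profiles.loc[g, "hazard_ratio_oe"]) if has_profile else np.nan,
                "flagged": not has_profile,
            })
    report = pd.DataFrame(rows).sort_values(
        ["group", "mean_path", "gene"], kind="mergesort").reset_index(drop=True)
    correlations: dict[str, TestResult] = {}
    for group, sub in [("all", report)] + [
            (g, report[report["group"] == g]) for g in selection]:
        ok = sub.dropna(subset=["mean_path", "neg_log_p"])
        degenerate = (len(ok) < 3 or ok["mean_path"].nunique() < 2
                      or ok["neg_log_p"].nunique() < 2)
        if degenerate:
            correlations[group] = TestResult(
                method="spearman", statistic=np.nan, p_value=1.0,
                n_per_group=(len(ok),), extra={"degenerate": True})
        else:
            rho, p = sps.spearmanr(ok["mean_path"], ok["neg_log_p"])
            correlations[group] = TestResult(
                method="spearman", statistic=float(rho),
                p_value=float(min(p, 1.0)), n_per_group=(len(ok),),
                extra={"degenerate": False})
    return report, correlations


def compare_prognosis_distributions(neg_log_p: pd.Series,
                                    partition: pd.Series) -> list[TestResult]:
    """Pairwise two-sample KS tests of -log10 p between gene classes.

    ``partition`` labels each gene (e.g. SUR/non-SUR or low/medium/high
    variability); every unordered label pair with two non-empty parts is
    compared with an asymptotic two-sample KS test.
    """
    shared = neg_log_p.index.intersection(partition.index)
    labels = sorted(partition.loc[shared].unique())
    results = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            xa = neg_log_p.loc[shared][partition.loc[shared] == la].to_numpy(float)
            xb = neg_log_p.loc[shared][partition.loc[shared] == lb].to_numpy(float)
            if xa.size == 0 or xb.size == 0:
                continue
            ks = sps.ks_2samp(xa, xb, method="asymp")
            results.append(TestResult(
                method="ks_2samp", statistic=float(ks.statistic),
                p_value=float(min(ks.pvalue, 1.0)),
                n_per_group=(xa.size, xb.size),
                extra={"pair": f"{la}_vs_{lb}"}))
    return results
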