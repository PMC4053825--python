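"""Stage 1 — gene-level summarization and per-tissue regulator-class comparisons.

Compares RPKM distributions of RNA-binding proteins against other regulator
classes (TFs, miRNAs, lncRNAs, other genes) tissue by tissue, using the
two-sample rank-sum (Mann-Whitney/Wilcoxon) test for pairwise contrasts and
the Kruskal-Wallis test across all classes.

The rank-sum test switches to exact enumeration over all rank assignments
for small samples (|a| + |b| <= EXACT_LIMIT), which handles ties correctly;
larger samples use the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, TestResult, ValidationError

#: total sample size at or below which the rank-sum test enumerates exactly
EXACT_LIMIT = 12


def gene_level_expression(transcripts: ExpressionMatrix,
                          transcript_map: pd.Series) -> ExpressionMatrix:
    """Collapse a transcript-level matrix to gene level.

    Each gene's value in a sample is the median over its transcripts'
    values in that sample.  Every transcript row must be present in
    ``transcript_map`` (transcript_id -> gene_id).
    """
    missing = transcripts.genes.difference(transcript_map.index)
    if len(missing):
        raise ValidationError(
            f"transcripts absent from transcript map: {sorted(missing)[:5]}"
        )
    genes = transcript_map.loc[transcripts.genes]
    collapsed = transcripts.values.groupby(genes.to_numpy()).median()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(values=collapsed, samples=transcripts.samples.copy())


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group ``a`` using midranks (tie-aware)."""
    n = len(a)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


@lru_cache(maxsize=4096)
def _exact_u_distribution(pooled: tuple[float, ...], n: int) -> np.ndarray:
    """Null distribution of U over all C(N, n) assignments of the pooled values."""
    pooled_arr = np.asarray(pooled, float)
    ranks = sps.rankdata(pooled_arr)
    offset = n * (n + 1) / 2.0
    us = [ranks[list(idx)].sum() - offset
          for idx in itertools.combinations(range(len(pooled)), n)]
    return np.asarray(us, float)


def rank_sum_test(a, b) -> TestResult:
    """Two-sided two-sample rank-sum (Mann-Whitney) test.

    Exact enumeration over all rank assignments when the pooled sample size
    is at most :data:`EXACT_LIMIT`; otherwise the normal approximation with
    tie correction and continuity correction.  The exact two-sided p-value
    is P(|U - nm/2| >= |u_obs - nm/2|) under the permutation null, which is
    symmetric in the two groups.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test requires two non-empty groups")
    n, m = len(a), len(b)
    u = _u_statistic(a, b)
    if n + m <= EXACT_LIMIT:
        dist = _exact_u_distribution(tuple(sorted(np.concatenate([a, b]))), n)
        center = n * m / 2.0
        dev = abs(u - center)
        p = float(np.mean(np.abs(dist - center) >= dev - 1e-9))
        method = "rank_sum_exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               use_continuity=True, method="asymptotic")
        p = float(res.pvalue)
        method = "rank_sum_normal"
    return TestResult(method=method, statistic=u, p_value=min(p, 1.0),
                      n_per_group=(n, m),
                      extra={"median_a": float(np.median(a)),
                             "median_b": float(np.median(b))})


def kruskal_wallis_test(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square reference (k-1 df)."""
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis_test requires >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("kruskal_wallis_test groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # all observations identical: H is 0 by construction
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    return TestResult(method="kruskal_wallis", statistic=float(h),
                      p_value=float(min(p, 1.0)),
                      n_per_group=tuple(len(g) for g in groups))


def compare_classes_per_tissue(expr: ExpressionMatrix,
                               annotation: pd.DataFrame,
                               contrasts: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-tissue regulator-class expression comparisons.

    For every tissue (sample column) run one rank-sum test per requested
    class pair plus one Kruskal-Wallis test across all annotated classes.
    ``annotation`` must cover every gene in ``expr`` and carry a
    ``regulator_class`` column.  Returns one row per tissue per test with
    the statistic, p-value, group sizes and group medians.
    """
    missing = expr.genes.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"annotation missing genes: {sorted(missing)[:5]}")
    classes = annotation.loc[expr.genes, "regulator_class"]
    present = sorted(classes.unique())
    for pair in contrasts:
        for cls in pair:
            if cls not in present:
                raise ValidationError(f"contrast names absent class {cls!r}")
    rows = []
    for tissue in expr.sample_ids:
        col = expr.values[tissue]
        by_class = {c: col[classes == c].to_numpy() for c in present}
        kw = kruskal_wallis_test([by_class[c] for c in present])
        rows.append({"tissue": tissue, "contrast": "all_classes",
                     "method": kw.method, "statistic": kw.statistic,
                     "p_value": kw.p_value,
                     "n_a": sum(kw.n_per_group), "n_b": np.nan,
                     "median_a": np.nan, "median_b": np.nan})
        for ca, cb in contrasts:
            rs = rank_sum_test(by_class[ca], by_class[cb])
            rows.append({"tissue": tissue, "contrast": f"{ca}_vs_{cb}",
                         "method": rs.method, "statistic": rs.statistic,
                         "p_value": rs.p_value,
                         "n_a": rs.n_per_group[0], "n_b": rs.n_per_group[1],
                         "median_a": rs.extra["median_a"],
                         "median_b": rs.extra["median_b"]})
    return pd.DataFrame(rows)
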