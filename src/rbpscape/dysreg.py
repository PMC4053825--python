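"""Stage 2 — fold-change profiling, SUR calling and variability classification.

Per-patient fold changes are the ratio of tumor expression to the matched
healthy-reference value, with a small pseudocount guarding zero
denominators.  Each gene x cancer cell is summarized by the median ratio,
its log2, and the raw (unscaled) MAD of the per-patient ratios.  A gene is
called strongly upregulated (SUR) when its median ratio reaches the
ninefold threshold in at least six of the profiled cancers; both threshold
and cancer count are configurable, and the threshold can optionally be
applied on the log2 scale instead of the plain ratio scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import (DysregulationCall, ExpressionMatrix, FoldChangeSummary,
                        TestResult, ValidationError, VariabilityClass)

DEFAULT_RATIO_THRESHOLD = 9.0
DEFAULT_MIN_CANCERS = 6
DEFAULT_PSEUDOCOUNT = 0.01


def patient_fold_changes(tumor: ExpressionMatrix, healthy: pd.Series,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene per-patient expression ratios (tumor + eps) / (healthy + eps).

    ``healthy`` holds one reference value per gene.  ``pseudocount=0`` is
    permitted only when no healthy value is zero.
    """
    missing = tumor.genes.difference(healthy.index)
    if len(missing):
        raise ValidationError(
            f"genes missing a healthy reference: {sorted(missing)[:5]}")
    h = healthy.loc[tumor.genes].to_numpy(float)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (h == 0).any():
        raise ValidationError("zero healthy expression requires pseudocount > 0")
    ratios = (tumor.values.to_numpy(float) + pseudocount) / (h[:, None] + pseudocount)
    return pd.DataFrame(ratios, index=tumor.genes, columns=tumor.sample_ids)


def summarize_fold_changes(ratios_by_cancer: dict[str, pd.DataFrame]) -> FoldChangeSummary:
    """Median / log2-median / MAD summaries of per-patient ratios, per cancer."""
    if not ratios_by_cancer:
        raise ValidationError("no cancers to summarize")
    cancers = list(ratios_by_cancer)
    genes = next(iter(ratios_by_cancer.values())).index
    med, mad, npat = {}, {}, {}
    for c, r in ratios_by_cancer.items():
        if r.shape[1] < 1:
            raise ValidationError(f"cancer {c!r} has no patients")
        if not r.index.equals(genes):
            raise ValidationError("gene sets differ between cancers")
        arr = r.to_numpy(float)
        m = np.median(arr, axis=1)
        med[c] = m
        mad[c] = np.median(np.abs(arr - m[:, None]), axis=1)
        npat[c] = r.shape[1]
    median_ratio = pd.DataFrame(med, index=genes)[cancers]
    mad_ratio = pd.DataFrame(mad, index=genes)[cancers]
    return FoldChangeSummary(
        patient_ratios=dict(ratios_by_cancer),
        median_ratio=median_ratio,
        log2_median_ratio=np.log2(median_ratio),
        mad_ratio=mad_ratio,
        n_patients=pd.Series(npat)[cancers],
    )


def classify_sur(summary: FoldChangeSummary,
                 ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                 min_cancers: int = DEFAULT_MIN_CANCERS,
                 scale: str = "ratio") -> DysregulationCall:
    """Call strongly-upregulated genes from median fold changes.

    A gene is SUR when its per-cancer median fold change is >= the
    threshold in at least ``min_cancers`` cancers.  ``scale`` selects
    whether the threshold applies to the plain median ratio (default) or to
    ``log2_median_ratio``.
    """
    if scale not in ("ratio", "log2"):
        raise ValidationError(f"unknown threshold scale {scale!r}")
    values = summary.median_ratio if scale == "ratio" else summary.log2_median_ratio
    if values.shape[1] < min_cancers:
        raise ValidationError(
            f"only {values.shape[1]} cancers available but min_cancers={min_cancers}")
    above = (values >= ratio_threshold).sum(axis=1)
    table = pd.DataFrame({"n_cancers_above": above,
                          "is_sur": above >= min_cancers})
    return DysregulationCall(table=table, ratio_threshold=ratio_threshold,
                             min_cancers=min_cancers, scale=scale)


def upper_quartile_flags(summary: FoldChangeSummary) -> pd.Series:
    """Flag genes whose cross-cancer median fold change sits in the top quartile.

    The per-gene score is the median over cancers of the per-cancer median
    ratio; a gene is flagged when its score is at or above the 75th
    percentile (linear interpolation) of all genes' scores.  With all
    scores equal every gene is flagged.
    """
    score = summary.median_ratio.median(axis=1)
    threshold = np.percentile(score.to_numpy(float), 75)
    return score >= threshold


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> TestResult:
    """Upper-tail hypergeometric over-representation test: P(X >= k).

    Drawing ``K`` genes from a universe of ``N`` containing ``n`` marked
    genes, the p-value is the probability of seeing at least the observed
    ``k`` marked genes in the draw.
    """
    if not (0 <= k <= min(K, n) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    p = float(sps.hypergeom.sf(k - 1, N, n, K))
    return TestResult(method="hypergeometric_upper", statistic=float(k),
                      p_value=min(max(p, 0.0), 1.0), n_per_group=(K, N),
                      extra={"population_successes": n})


def _paired_t_p(diff: np.ndarray) -> float:
    """Two-sided paired-t p-value on per-patient differences.

    Degenerate conventions: all-zero differences give p = 1 (no evidence of
    change); constant non-zero differences give p = 0 (t diverges).
    """
    sd = diff.std(ddof=1)
    if sd == 0:
        return 1.0 if np.allclose(diff, 0) else 0.0
    t = diff.mean() / (sd / np.sqrt(len(diff)))
    return float(2 * sps.t.sf(abs(t), df=len(diff) - 1))


def tumor_matched_tests(cohorts: dict[str, tuple[ExpressionMatrix, ExpressionMatrix | None]],
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        p_cut: float = 0.001) -> tuple[pd.DataFrame, pd.Series]:
    """Paired t-tests of tumor vs matched-normal expression, per gene per cancer.

    The test is a two-sided paired t on log2(tumor + eps) - log2(normal + eps)
    restricted to patients contributing both samples.  Cancers with fewer
    than two matched pairs are untestable (NaN) and excluded from the
    per-gene count of cancers significant at ``p_cut``.

    Returns ``(p_values, n_significant)`` with ``p_values`` genes x cancers.
    """
    pmats = {}
    genes = None
    for cancer, (tumor, normal) in cohorts.items():
        if genes is None:
            genes = tumor.genes
        if normal is None:
            pmats[cancer] = pd.Series(np.nan, index=genes)
            continue
        t_meta = tumor.samples[tumor.samples["kind"] == "tumor"]
        n_meta = normal.samples[normal.samples["kind"] == "matched_normal"]
        shared = [p for p in t_meta["patient_id"] if p in set(n_meta["patient_id"])]
        if len(shared) < 2:
            pmats[cancer] = pd.Series(np.nan, index=genes)
            continue
        t_cols = t_meta.index[t_meta["patient_id"].isin(shared)]
        n_cols = n_meta.index[n_meta["patient_id"].isin(shared)]
        t_by_patient = tumor.values[t_cols]
        t_by_patient.columns = t_meta.loc[t_cols, "patient_id"]
        n_by_patient = normal.values[n_cols]
        n_by_patient.columns = n_meta.loc[n_cols, "patient_id"]
        diffs = (np.log2(t_by_patient[shared] + pseudocount)
                 - np.log2(n_by_patient[shared] + pseudocount)).to_numpy(float)
        pmats[cancer] = pd.Series(
            [_paired_t_p(d) for d in diffs], index=genes)
    p_values = pd.DataFrame(pmats)
    n_significant = (p_values < p_cut).sum(axis=1)
    return p_values, n_significant


def classify_variability(summary: FoldChangeSummary, cancer: str,
                         q_low: float = 25.0, q_high: float = 75.0) -> VariabilityClass:
    """Partition genes into low/medium/high fold-change variability.

    High: MAD strictly above the ``q_high`` percentile of that cancer's MAD
    distribution; low: strictly below ``q_low``; ties at either bound fall
    to medium.  Percentiles use linear interpolation.
    """
    if cancer not in summary.mad_ratio.columns:
        raise ValidationError(f"unknown cancer {cancer!r}")
    mad = summary.mad_ratio[cancer]
    if len(mad) < 4:
        raise ValidationError("variability classification needs >= 4 genes")
    lo = np.percentile(mad.to_numpy(float), q_low)
    hi = np.percentile(mad.to_numpy(float), q_high)
    label = pd.Series("medium", index=mad.index)
    label[mad > hi] = "high"
    label[mad < lo] = "low"
    return VariabilityClass(cancer=cancer, mad=mad, label=label,
                            q_low=q_low, q_high=q_high)


def cluster_cancers(log2_ratio_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of cancers (columns).

    Distance between two cancers is 1 - Pearson correlation of their
    per-gene log2 median fold changes.  Returns the scipy linkage matrix
    and the column labels in input order.  Zero-variance columns are
    rejected because their correlation is undefined.
    """
    if log2_ratio_matrix.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 cancers")
    arr = log2_ratio_matrix.to_numpy(float)
    sd = arr.std(axis=0)
    flat = [c for c, s in zip(log2_ratio_matrix.columns, sd) if s == 0]
    if flat:
        raise ValidationError(f"zero-variance cancer column(s): {flat}")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return z, list(log2_ratio_matrix.columns)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _cnt) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + i] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[n + i] = h
    return nodes[n + len(z) - 1] + ";"
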