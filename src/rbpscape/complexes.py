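"""Stage 4 — protein-complex membership statistics.

For each gene, count the complexes it belongs to and the mean size of those
complexes, then compare the two statistics between SUR and non-SUR genes
and correlate each with the extent of dysregulation.  Genes outside every
complex are reported with a zero count and, by default, excluded from the
group comparisons (only complex members are compared).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ComplexStats, TestResult
from .profiling import rank_sum_test

log = logging.getLogger(__name__)


def complex_membership_stats(catalog: pd.DataFrame, genes) -> ComplexStats:
    """Per-gene complex membership count and mean complex size.

    ``catalog`` is indexed by complex id with columns ``name`` and
    ``members`` (tuple of gene symbols).  Genes in no complex get
    ``n_complexes = 0`` and ``mean_size = NaN``.
    """
    genes = sorted(set(genes))
    counts = {g: 0 for g in genes}
    size_sums = {g: 0.0 for g in genes}
    gene_set = set(genes)
    for _cid, row in catalog.iterrows():
        members = row["members"]
        size = len(members)
        for m in members:
            if m in gene_set:
                counts[m] += 1
                size_sums[m] += size
    n = pd.Series(counts, dtype=int)
    mean_size = pd.Series(
        {g: (size_sums[g] / counts[g]) if counts[g] else np.nan for g in genes})
    table = pd.DataFrame({"n_complexes": n, "mean_size": mean_size})
    table.index.name = "gene"
    return ComplexStats(table=table)


def compare_complex_stats(sur_stats: ComplexStats, nonsur_stats: ComplexStats,
                          log2_fold_change: pd.Series | None = None,
                          include_zeros: bool = False) -> dict[str, TestResult]:
    """Compare complex membership between SUR and non-SUR genes.

    Rank-sum tests on ``n_complexes`` and ``mean_size`` (complex members
    only unless ``include_zeros``), plus Spearman correlations of each
    statistic with the per-gene log2 median fold change when provided.
    Degenerate correlations (constant input) are flagged rather than
    reported as significant.
    """
    results: dict[str, TestResult] = {}
    a_all, b_all = sur_stats.table, nonsur_stats.table
    if include_zeros:
        a, b = a_all, b_all
    else:
        a = a_all[a_all["n_complexes"] > 0]
        b = b_all[b_all["n_complexes"] > 0]
    if len(a) == 0 or len(b) == 0:
        log.warning("complex comparison skipped: a group has no complex members")
        return results
    results["n_complexes"] = rank_sum_test(a["n_complexes"], b["n_complexes"])
    results["mean_size"] = rank_sum_test(a["mean_size"].dropna(),
                                         b["mean_size"].dropna())
    if log2_fold_change is not None:
        both = pd.concat([a, b])
        fc = log2_fold_change.reindex(both.index)
        for col in ("n_complexes", "mean_size"):
            x = both[col]
            ok = x.notna() & fc.notna()
            degenerate = ok.sum() < 3 or x[ok].nunique() < 2 or fc[ok].nunique() < 2
            if degenerate:
                results[f"spearman_{col}"] = TestResult(
                    method="spearman", statistic=0.0, p_value=1.0,
                    n_per_group=(int(ok.sum()),), extra={"degenerate": True})
            else:
                rho, p = sps.spearmanr(x[ok], fc[ok])
                results[f"spearman_{col}"] = TestResult(
                    method="spearman", statistic=float(rho),
                    p_value=float(min(p, 1.0)), n_per_group=(int(ok.sum()),),
                    extra={"degenerate": False})
    return results


def membership_conservation_check(catalog: pd.DataFrame, genes) -> bool:
    """Sum of per-gene counts equals sum of complex sizes restricted to the universe."""
    stats = complex_membership_stats(catalog, genes)
    gene_set = set(genes)
    total = sum(sum(1 for m in row["members"] if m in gene_set)
                for _c, row in catalog.iterrows())
    return int(stats.table["n_complexes"].sum()) == total
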