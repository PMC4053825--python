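"""Stage 3 — PPI network metrics and group shortest-path profiling.

The protein-protein interaction network is a simple undirected graph of
gene symbols.  This module computes normalized centralities, shortest-path
distributions within gene groups (SUR vs non-SUR), per-node mean distances
to each group, path-length-ranked gene selections, and the comparison of
interaction-partner counts across expression-variability classes.

Unreachable pairs are excluded from distributions and means (and counted),
rather than imputed with a sentinel distance.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import TestResult, ValidationError, VariabilityClass
from .profiling import rank_sum_test

log = logging.getLogger(__name__)


def compute_node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Normalized degree, closeness, betweenness and clustering per node.

    degree_norm = degree / (n-1); closeness follows the Wasserman-Faust
    component correction (reachable count over distance sum, scaled by the
    reachable fraction of the graph); betweenness_norm = raw x 2/((n-1)(n-2));
    clustering is the local clustering coefficient.  With fewer than three
    nodes betweenness is undefined and reported as NaN.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValidationError("empty network")
    nodes = sorted(net.nodes)
    degree = pd.Series(dict(net.degree()), dtype=float).loc[nodes]
    out = pd.DataFrame(index=pd.Index(nodes, name="gene"))
    out["degree"] = degree
    out["degree_norm"] = degree / (n - 1) if n > 1 else 0.0
    out["closeness_norm"] = pd.Series(
        nx.closeness_centrality(net, wf_improved=True)).loc[nodes]
    if n >= 3:
        out["betweenness_norm"] = pd.Series(
            nx.betweenness_centrality(net, normalized=True)).loc[nodes]
    else:
        log.warning("betweenness omitted: need >= 3 nodes, have %d", n)
        out["betweenness_norm"] = np.nan
    out["clustering"] = pd.Series(nx.clustering(net)).loc[nodes]
    return out


def group_pairwise_distances(net: nx.Graph, group) -> tuple[np.ndarray, int]:
    """Shortest-path lengths over unordered within-group pairs.

    Returns ``(lengths, n_unreachable)`` where unreachable pairs are
    excluded from ``lengths`` and counted separately.  A group smaller
    than two yields an empty result.
    """
    group = sorted(set(group))
    missing = [g for g in group if g not in net]
    if missing:
        raise ValidationError(f"group members absent from network: {missing[:5]}")
    if len(group) < 2:
        return np.array([], dtype=float), 0
    idx = {g: i for i, g in enumerate(group)}
    lengths: list[int] = []
    unreachable = 0
    for i, src in enumerate(group):
        dist = nx.single_source_shortest_path_length(net, src)
        for tgt in group[i + 1:]:
            d = dist.get(tgt)
            if d is None:
                unreachable += 1
            else:
                lengths.append(d)
    return np.asarray(lengths, float), unreachable


def compare_distance_distributions(d_sur, d_nonsur) -> TestResult:
    """Two-sided rank-sum comparison of two path-length distributions."""
    d_sur = np.asarray(d_sur, float)
    d_nonsur = np.asarray(d_nonsur, float)
    if d_sur.size == 0 or d_nonsur.size == 0:
        raise ValidationError("empty distance distribution")
    res = rank_sum_test(d_sur, d_nonsur)
    res.extra["median_sur"] = float(np.median(d_sur))
    res.extra["median_nonsur"] = float(np.median(d_nonsur))
    return res


def mean_path_profiles(net: nx.Graph, sur) -> pd.DataFrame:
    """Per-node mean shortest-path distance to the SUR set, the non-SUR set
    and all other nodes.

    Means are taken over reachable targets only, always excluding the node
    itself; nodes with no reachable target in a set get NaN there, with the
    reachable count reported alongside.
    """
    sur = set(sur)
    missing = sur.difference(net.nodes)
    if missing:
        raise ValidationError(f"SUR genes absent from network: {sorted(missing)[:5]}")
    nodes = sorted(net.nodes)
    rows = {}
    for src in nodes:
        dist = nx.single_source_shortest_path_length(net, src)
        d_sur = [d for t, d in dist.items() if t != src and t in sur]
        d_non = [d for t, d in dist.items() if t != src and t not in sur]
        d_all = d_sur + d_non
        rows[src] = {
            "mean_dist_to_sur": float(np.mean(d_sur)) if d_sur else np.nan,
            "n_reachable_sur": len(d_sur),
            "mean_dist_to_nonsur": float(np.mean(d_non)) if d_non else np.nan,
            "n_reachable_nonsur": len(d_non),
            "mean_dist_all": float(np.mean(d_all)) if d_all else np.nan,
            "n_reachable_all": len(d_all),
            "is_sur": src in sur,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def rank_and_select(profiles: pd.DataFrame, key: str, k: int = 5,
                    seed: int = 0) -> dict[str, list[str]]:
    """Select the k shortest, k longest and k random intermediate genes by
    mean path length.

    Genes with an undefined key are dropped; at least 3k defined genes are
    required.  Ties at a selection boundary break lexicographically by gene
    symbol; the intermediate draw uses its own seeded generator, so the
    three sets are disjoint and the selection is reproducible.
    """
    ranked = profiles[[key]].dropna().copy()
    if len(ranked) < 3 * k:
        raise ValidationError(
            f"need >= {3 * k} genes with defined {key!r}, have {len(ranked)}")
    # lexsort: primary key = mean path, secondary = gene symbol (tie-break)
    order = ranked.iloc[np.lexsort((ranked.index.to_numpy(),
                                    ranked[key].to_numpy()))]
    genes = list(order.index)
    shortest = genes[:k]
    longest = genes[-k:]
    middle = genes[k:-k]
    rng = np.random.default_rng([seed, 7])
    intermediate = sorted(rng.choice(middle, size=k, replace=False).tolist())
    return {"shortest": shortest, "longest": longest,
            "intermediate": intermediate}


def degree_vs_variability(classes: VariabilityClass,
                          metrics: pd.DataFrame) -> list[TestResult]:
    """KS comparisons of interaction counts between variability classes.

    For each pair among (low, medium, high) run a two-sample
    Kolmogorov-Smirnov test (asymptotic p) on the raw degree distributions.
    Pairs involving an empty class are skipped with a warning.
    """
    shared = classes.label.index.intersection(metrics.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared between classes and metrics")
    label = classes.label.loc[shared]
    degree = metrics.loc[shared, "degree"]
    results = []
    levels = ("low", "medium", "high")
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            da = degree[label == la].to_numpy(float)
            db = degree[label == lb].to_numpy(float)
            if da.size == 0 or db.size == 0:
                log.warning("variability pair %s vs %s skipped: empty class",
                            la, lb)
                continue
            ks = sps.ks_2samp(da, db, method="asymp")
            results.append(TestResult(
                method="ks_2samp", statistic=float(ks.statistic),
                p_value=float(min(ks.pvalue, 1.0)),
                n_per_group=(da.size, db.size),
                extra={"pair": f"{la}_vs_{lb}",
                       "median_a": float(np.median(da)),
                       "median_b": float(np.median(db))}))
    return results
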