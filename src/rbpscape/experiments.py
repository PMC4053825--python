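"""Parameter-recovery and calibration studies over the synthetic generators.

Each function runs one planted-signal or null experiment at the study's
default conditions and returns plain numbers (rates, medians, agreement
fractions).  They are the backbone of the acceptance checks and of the
numbered analysis drivers; everything is deterministic given the base
seed.

Oracle comparisons deliberately go through independent machinery
(scipy's Floyd-Warshall for shortest paths, scipy's exact Mann-Whitney
and direct subset enumeration for the small-sample tests) so agreement is
a two-route check, not a tautology.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import floyd_warshall

from . import dysreg, network as net
from .datatypes import FoldChangeSummary
from .profiling import rank_sum_test
from .survival import km_curve, logrank_test
from .synth import (CANCER_TISSUE, PlantSpec, generate_cancer_cohorts,
                    generate_gene_universe, generate_healthy_expression,
                    generate_ppi_network, generate_survival_cohort,
                    choose_sur_genes, couple_noise_to_degree, stage_rng)


def _cohort_summary(seed: int, **spec_kwargs) -> tuple[PlantSpec, "SyntheticPieces"]:
    """Generate universe + healthy + cohorts and summarize fold changes."""
    spec = PlantSpec(seed=seed, **spec_kwargs)
    ann = generate_gene_universe(spec)
    sur = choose_sur_genes(ann, spec)
    healthy = generate_healthy_expression(
        ann, spec.n_tissues, spec.class_location_shift,
        stage_rng(seed, "healthy"))
    cohorts, folds = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
    ratios = {c: dysreg.patient_fold_changes(t, healthy.values[CANCER_TISSUE[c]])
              for c, (t, _n) in cohorts.items()}
    summary = dysreg.summarize_fold_changes(ratios)
    return spec, (ann, sur, summary)


# ------------------------------------------------------------ SUR recovery

def sur_recovery(seeds) -> dict:
    """Sensitivity/specificity of SUR calling against the planted gene set.

    Default study conditions: 1,000 genes, 9 cancers x 50 patients,
    25 planted SUR genes (folds 10-50 in 7 cancers), background folds
    0.5-3, patient noise CV 0.3.
    """
    sens, spec_rates = [], []
    for seed in seeds:
        _spec, (ann, planted, summary) = _cohort_summary(int(seed))
        call = dysreg.classify_sur(summary)
        called = call.sur_genes
        tp = len(called & planted)
        fp = len(called - planted)
        neg = len(ann) - len(planted)
        sens.append(tp / len(planted))
        spec_rates.append((neg - fp) / neg)
    return {"sensitivity": float(np.mean(sens)),
            "specificity": float(np.mean(spec_rates)),
            "n_seeds": len(list(seeds))}


def sur_boundary_examples() -> float:
    """Fraction of the two threshold-boundary cases called correctly.

    Median ratios of 10 in 6 of 9 cancers -> SUR; 10 in only 5 of 9 -> not.
    """
    cancers = [f"c{i}" for i in range(9)]
    genes = pd.Index(["six_of_nine", "five_of_nine"], name="gene_id")
    med = pd.DataFrame(
        [[10.0] * 6 + [1.0] * 3, [10.0] * 5 + [1.0] * 4],
        index=genes, columns=cancers)
    summary = FoldChangeSummary(
        patient_ratios={c: med[[c]] for c in cancers},
        median_ratio=med, log2_median_ratio=np.log2(med),
        mad_ratio=med * 0.0, n_patients=pd.Series(1, index=cancers))
    call = dysreg.classify_sur(summary, ratio_threshold=9.0, min_cancers=6)
    correct = (bool(call.table.loc["six_of_nine", "is_sur"])
               + (not call.table.loc["five_of_nine", "is_sur"]))
    return correct / 2.0


# ---------------------------------------------------- shortest-path oracle

def _oracle_distances(g: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    dist = floyd_warshall(adj, directed=False, unweighted=True)
    return nodes, dist

def _oracle_betweenness(dist: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Betweenness from shortest-path counts via the distance recurrence."""
    n = dist.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = (adj[:, t] > 0) & (dist[s] == dist[s, t] - 1)
            sigma[s, t] = sigma[s, preds].sum()
    bet = np.zeros(n)
    for v in range(n):
        for s in range(n):
            if s == v:
                continue
            for t in range(s + 1, n):
                if t == v or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bet[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bet


def shortest_path_oracle_agreement(n_graphs: int = 100, max_n: int = 50,
                                   seed: int = 0) -> float:
    """Fraction of random graphs where path computations match brute force.

    Checks group_pairwise_distances, mean_path_profiles and
    compute_node_metrics against an all-pairs Floyd-Warshall recomputation
    (plus a path-count betweenness recurrence) on G(n, p) graphs with
    n <= ``max_n``, including disconnected ones.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_graphs):
        n = int(rng.integers(5, max_n + 1))
        p = float(rng.uniform(0.03, 0.25))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        nodes, dist = _oracle_distances(g)
        adj = nx.to_numpy_array(g, nodelist=nodes, weight=None)
        k = max(2, n // 4)
        group = sorted(rng.choice(nodes, size=k, replace=False).tolist())
        # within-group pair distances
        lengths, unreach = net.group_pairwise_distances(g, group)
        gi = [nodes.index(v) for v in group]
        pairs = [dist[a, b] for a, b in itertools.combinations(gi, 2)]
        want = sorted(d for d in pairs if np.isfinite(d))
        ok = (sorted(lengths.tolist()) == want
              and unreach == sum(1 for d in pairs if not np.isfinite(d)))
        # per-node mean distances to the group / complement
        profiles = net.mean_path_profiles(g, group)
        for vi, v in enumerate(nodes):
            for key, members in (("mean_dist_to_sur", set(group)),
                                 ("mean_dist_to_nonsur", set(nodes) - set(group))):
                ds = [dist[vi, nodes.index(t)] for t in members if t != v]
                ds = [d for d in ds if np.isfinite(d)]
                got = profiles.loc[v, key]
                ok &= (np.isnan(got) if not ds
                       else bool(np.isclose(got, np.mean(ds))))
        # centralities
        metrics = net.compute_node_metrics(g)
        deg = adj.sum(axis=1)
        ok &= np.allclose(metrics["degree_norm"].to_numpy(),
                          deg / (n - 1))
        clo = np.zeros(n)
        for vi in range(n):
            finite = np.isfinite(dist[vi]) & (np.arange(n) != vi)
            r = finite.sum()
            if r > 0:
                clo[vi] = (r / dist[vi, finite].sum()) * (r / (n - 1))
        ok &= np.allclose(metrics["closeness_norm"].to_numpy(), clo)
        bet = _oracle_betweenness(dist, adj) * 2.0 / ((n - 1) * (n - 2))
        ok &= np.allclose(metrics["betweenness_norm"].to_numpy(), bet)
        agree += bool(ok)
    return agree / n_graphs


# ------------------------------------------------- planted-module recovery

def _module_experiment(seed: int, module_density: float) -> tuple[float, float, float]:
    """One 500-node network; returns (median_sur, median_non, rank-sum p)."""
    spec = PlantSpec(n_genes=500, n_sur=25, module_density=module_density,
                     seed=seed)
    ann = generate_gene_universe(spec)
    sur = choose_sur_genes(ann, spec)
    g = generate_ppi_network(ann, sur, spec)
    d_sur, _ = net.group_pairwise_distances(g, sur)
    d_non, _ = net.group_pairwise_distances(g, set(ann.index) - sur)
    res = net.compare_distance_distributions(d_sur, d_non)
    return (res.extra["median_sur"], res.extra["median_nonsur"], res.p_value)


def planted_module_recovery(seeds) -> float:
    """Fraction of planted-module seeds with shorter within-SUR paths (p < 0.01)."""
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        m_sur, m_non, p = _module_experiment(int(seed), module_density=0.3)
        hits += (m_sur < m_non) and (p < 0.01)
    return hits / len(seeds)


def module_null_rejection(seeds, alpha: float = 0.05) -> float:
    """Rank-sum rejection rate on unplanted networks (no module wiring)."""
    seeds = list(seeds)
    rej = 0
    for seed in seeds:
        _m1, _m2, p = _module_experiment(int(seed), module_density=0.0)
        rej += p < alpha
    return rej / len(seeds)


# --------------------------------------------------- exact-test oracles

@lru_cache(maxsize=None)
def _hypergeom_tail_oracle(N: int, n: int, K: int) -> tuple[float, ...]:
    """P(X >= k) for k = 0..min(K, n) by enumerating all C(N, K) draws."""
    marked = set(range(n))
    counts = np.zeros(min(K, n) + 1)
    total = 0
    for draw in itertools.combinations(range(N), K):
        counts[len(marked.intersection(draw))] += 1
        total += 1
    tail = np.cumsum(counts[::-1])[::-1] / total
    return tuple(tail)


def hypergeometric_oracle_agreement(max_N: int = 12,
                                    rtol: float = 1e-9) -> float:
    """Agreement fraction of the enrichment test with exhaustive enumeration.

    Every consistent (N, n, K, k) with N <= ``max_N`` is checked.
    """
    checked = agree = 0
    for N in range(1, max_N + 1):
        for n in range(0, N + 1):
            for K in range(0, N + 1):
                tail = _hypergeom_tail_oracle(N, n, K)
                for k in range(0, min(K, n) + 1):
                    got = dysreg.hypergeometric_enrichment(k, K, n, N).p_value
                    agree += bool(np.isclose(got, tail[k], rtol=rtol, atol=1e-12))
                    checked += 1
    return agree / checked


def rank_sum_oracle_agreement(max_N: int = 12) -> float:
    """Agreement of the exact rank-sum branch with scipy's exact enumeration.

    All tie-free instances on rank universes up to ``max_N``: for every
    universe size N and group size n, every subset of ranks {1..N} forms
    group a.  scipy's exact Mann-Whitney is the independent oracle.
    """
    checked = agree = 0
    for N in range(2, max_N + 1):
        universe = np.arange(1.0, N + 1)
        for n in range(1, N):
            for combo in itertools.combinations(range(N), n):
                a = universe[list(combo)]
                b = np.delete(universe, list(combo))
                got = rank_sum_test(a, b).p_value
                want = sps.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact").pvalue
                agree += bool(np.isclose(got, float(want), rtol=1e-9))
                checked += 1
    return agree / checked


# --------------------------------------------- MAD-degree (variability)

def _variability_experiment(seed: int, rho: float,
                            module_density: float) -> tuple[bool, float]:
    """Breast-cohort variability classes vs degree.

    Returns (medians monotone low<=medium<=high, low-vs-high KS p).
    """
    spec = PlantSpec(seed=seed, mad_degree_rho=rho,
                     module_density=module_density)
    ann = generate_gene_universe(spec)
    sur = choose_sur_genes(ann, spec)
    healthy = generate_healthy_expression(
        ann, spec.n_tissues, spec.class_location_shift,
        stage_rng(seed, "healthy"))
    g = generate_ppi_network(ann, sur, spec)
    deg = pd.Series(dict(g.degree()), dtype=float).loc[ann.index]
    cv = couple_noise_to_degree(deg, spec)
    breast_spec = PlantSpec(
        seed=seed, n_genes=spec.n_genes, mad_degree_rho=rho,
        patients_per_cancer={"breast_ca": 50}, n_cancers=1,
        sur_cancers_per_gene=1, min_cancers=1,
        module_density=module_density)
    cohorts, _ = generate_cancer_cohorts(healthy, breast_spec, sur_genes=sur,
                                         gene_noise_cv=cv)
    tumor, _n = cohorts["breast_ca"]
    ratios = {"breast_ca": dysreg.patient_fold_changes(
        tumor, healthy.values["breast"])}
    summary = dysreg.summarize_fold_changes(ratios)
    vc = dysreg.classify_variability(summary, "breast_ca")
    results = net.degree_vs_variability(vc, pd.DataFrame({"degree": deg}))
    by_pair = {r.extra["pair"]: r for r in results}
    med = {lvl: float(deg[vc.label == lvl].median())
           for lvl in ("low", "medium", "high")}
    monotone = med["low"] <= med["medium"] <= med["high"]
    return monotone, by_pair["low_vs_high"].p_value


def mad_degree_recovery(seeds, rho: float = 0.6) -> float:
    """Fraction of seeds with monotone class degrees and low-vs-high KS p < 0.01."""
    seeds = list(seeds)
    hits = 0
    for seed in seeds:
        monotone, p = _variability_experiment(int(seed), rho,
                                              module_density=0.3)
        hits += monotone and (p < 0.01)
    return hits / len(seeds)


def mad_degree_null_rejection(seeds, alpha: float = 0.05) -> float:
    """Low-vs-high KS rejection with no planted coupling (rho = 0, no module)."""
    seeds = list(seeds)
    rej = 0
    for seed in seeds:
        _mono, p = _variability_experiment(int(seed), rho=0.0,
                                           module_density=0.0)
        rej += p < alpha
    return rej / len(seeds)


# ----------------------------------------------------- survival engine

def km_empirical_max_error(n_cohorts: int = 200, seed: int = 0) -> float:
    """Max |KM - empirical survival| over random fully-observed cohorts."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cohorts):
        n = int(rng.integers(1, 60))
        times = rng.exponential(5.0, n) + 1e-6
        curve = km_curve(times, np.ones(n, int))
        for u, s in zip(curve.event_times, curve.survival):
            emp = np.mean(times > u)
            worst = max(worst, abs(s - emp))
    return worst


def logrank_type1_error(n_reps: int = 2000, n: int = 200, seed: int = 0,
                        censor_rate: float = 0.2, alpha: float = 0.05) -> float:
    """Rejection rate of the log-rank test under a planted hazard ratio of 1."""
    rej = 0
    for i in range(n_reps):
        cohort = generate_survival_cohort(
            n, {"gene": 1.0}, censor_rate,
            np.random.default_rng([seed, 11, i]))
        expr = cohort.expression.loc["gene"]
        high = expr.index[expr > expr.median()]
        low = expr.index[expr <= expr.median()]
        res = logrank_test(cohort.data.loc[high, "time"],
                           cohort.data.loc[high, "event"],
                           cohort.data.loc[low, "time"],
                           cohort.data.loc[low, "event"])
        rej += res.p_value < alpha
    return rej / n_reps


def hr_recovery(n_reps: int = 200, n: int = 300, hr: float = 3.0,
                seed: int = 0, censor_rate: float = 0.2,
                alpha: float = 0.05) -> dict:
    """Median observed/expected HR estimate and power at a planted HR."""
    estimates, rejections = [], 0
    for i in range(n_reps):
        cohort = generate_survival_cohort(
            n, {"gene": hr}, censor_rate,
            np.random.default_rng([seed, 13, i]))
        expr = cohort.expression.loc["gene"]
        high = expr.index[expr > expr.median()]
        low = expr.index[expr <= expr.median()]
        res = logrank_test(cohort.data.loc[high, "time"],
                           cohort.data.loc[high, "event"],
                           cohort.data.loc[low, "time"],
                           cohort.data.loc[low, "event"])
        estimates.append(res.extra["hazard_ratio_oe"])
        rejections += res.p_value < alpha
    return {"median_hr_oe": float(np.median(estimates)),
            "power": rejections / n_reps}


# ------------------------------------------------- variability partition

def variability_partition_exact(n_vectors: int = 100, n_genes: int = 100,
                                seed: int = 0, tol_genes: int = 1) -> float:
    """Fraction of tie-free MAD vectors split into 25/50/25 (+/- tol genes)."""
    rng = np.random.default_rng(seed)
    ok = 0
    cancers = ["c0"]
    for _ in range(n_vectors):
        mad = pd.Series(rng.permutation(np.linspace(0.1, 10.0, n_genes))
                        + rng.uniform(0, 1e-6, n_genes),
                        index=[f"g{i}" for i in range(n_genes)])
        med = pd.DataFrame({"c0": np.ones(n_genes)}, index=mad.index)
        summary = FoldChangeSummary(
            patient_ratios={"c0": med}, median_ratio=med,
            log2_median_ratio=np.log2(med),
            mad_ratio=pd.DataFrame({"c0": mad}),
            n_patients=pd.Series([1], index=cancers))
        vc = dysreg.classify_variability(summary, "c0")
        counts = vc.label.value_counts()
        ok += (abs(counts.get("low", 0) - n_genes // 4) <= tol_genes
               and abs(counts.get("high", 0) - n_genes // 4) <= tol_genes
               and abs(counts.get("medium", 0) - n_genes // 2) <= 2 * tol_genes)
    return ok / n_vectors


# ----------------------------------------------------- determinism

def pipeline_determinism(workdir, seed: int = 0) -> bool:
    """run-all twice with the same config: are all outputs byte-identical?"""
    from pathlib import Path
    from .pipeline import RunConfig, run_pipeline

    workdir = Path(workdir)
    digests = []
    for tag in ("a", "b"):
        out = workdir / tag
        cfg = RunConfig(seed=seed, outdir=str(out))
        run_pipeline(cfg)
        digest = {}
        for p in sorted(out.rglob("*")):
            if p.is_file():
                digest[p.relative_to(out)] = p.read_bytes()
        digests.append(digest)
    a, b = digests
    return set(a) == set(b) and all(a[k] == b[k] for k in a)
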