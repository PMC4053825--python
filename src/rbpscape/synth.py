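"""Synthetic-data generators with planted statistical structure.

Every input the pipeline consumes is generated here: a healthy-tissue
expression reference, per-cancer tumor cohorts with optional matched
normals, a gene annotation with regulator classes, a PPI network, a
protein-complex catalog and a survival cohort.  Each generator plants a
recoverable signal:

* a class-wise location shift so RBPs are more highly expressed than other
  classes in every healthy tissue;
* a designated SUR gene set whose tumor/healthy fold changes fall in a
  range strictly above the calling threshold in a fixed number of cancers,
  against background fold changes strictly below it;
* a dense module wiring the SUR genes together inside a heavy-tailed
  (preferential-attachment) network, so within-SUR shortest paths are
  shorter than within-non-SUR paths;
* a controllable rank correlation between a gene's per-patient noise level
  (hence its fold-change MAD) and its network degree;
* per-gene hazard ratios acting on the high-expression half of a survival
  cohort with exponential event times.

Expression is log-normal per class (strictly positive, heavy right tail,
like RPKM data); patient noise is multiplicative log-normal with median 1
so the planted fold equals the expected median ratio.  All generators are
deterministic given the seed: every stage draws from its own generator
derived from ``(seed, stage_id)``, so adding a stage never perturbs
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (ExpressionMatrix, REGULATOR_CLASSES, SurvivalCohort,
                        ValidationError)

#: canonical healthy tissues (Human BodyMap-style panel)
TISSUES = (
    "adipose", "adrenal", "brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "lymph_node", "ovary", "prostate", "skeletal_muscle",
    "testis", "thyroid", "white_blood_cells",
)

#: default cancer labels and the healthy tissue each is profiled against
#: (two lung cancers share one tissue: 9 cancers over 8 tissues)
CANCER_TISSUE = {
    "breast_ca": "breast",
    "brain_lgg": "brain",
    "colon_ad": "colon",
    "kidney_rcc": "kidney",
    "liver_hcc": "liver",
    "lung_ad": "lung",
    "lung_sq": "lung",
    "prostate_ad": "prostate",
    "thyroid_ca": "thyroid",
}

#: sub-stream ids: one generator per stage derived from (seed, id)
_STAGE = {"universe": 0, "healthy": 1, "network": 2, "noise": 3,
          "cohorts": 4, "complexes": 5, "survival": 6, "selection": 7}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    return np.random.default_rng([int(seed), _STAGE[stage]])


def _noise_sigma(cv: float) -> float:
    """Log-sd of a median-1 log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv ** 2)))


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of the planted synthetic study.

    Defaults are the desk-scale study conditions: 1,000 genes over five
    regulator classes, nine cancers of 50 patients each against a
    16-tissue healthy reference, 25 planted SUR genes with true fold
    changes in [10, 50] in exactly 7 of 9 cancers, background folds in
    [0.5, 3], and per-patient multiplicative noise with CV 0.3.
    """

    n_genes: int = 1000
    class_proportions: Mapping[str, float] = field(default_factory=lambda: {
        "RBP": 0.25, "TF": 0.12, "miRNA": 0.05, "lncRNA": 0.18, "other": 0.40})
    n_cancers: int = 9
    patients_per_cancer: Mapping[str, int] | None = None
    n_sur: int = 25
    sur_genes: frozenset | None = None
    sur_fold_range: tuple[float, float] = (10.0, 50.0)
    sur_cancers_per_gene: int = 7
    background_fold_range: tuple[float, float] = (0.5, 3.0)
    patient_noise_cv: float = 0.3
    mad_degree_rho: float = 0.0
    ratio_threshold: float = 9.0
    min_cancers: int = 6
    module_density: float = 0.3
    ba_m: int = 3
    class_location_shift: Mapping[str, float] = field(default_factory=lambda: {
        "RBP": float(np.log(4.0)), "TF": 0.0, "miRNA": float(-np.log(2.0)),
        "lncRNA": float(-np.log(2.0)), "other": 0.0})
    n_tissues: int = 16
    matched_normal_fraction: float = 0.5
    survival_n_patients: int = 300
    survival_censor_rate: float = 0.2
    seed: int = 0

    def cancers(self) -> dict[str, int]:
        if self.patients_per_cancer is not None:
            return dict(self.patients_per_cancer)
        labels = list(CANCER_TISSUE)[: self.n_cancers]
        return {c: 50 for c in labels}

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(REGULATOR_CLASSES)
        if unknown:
            raise ValidationError(f"unknown regulator class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValidationError("class proportions must be non-negative")
        cancers = self.cancers()
        if self.n_cancers != len(cancers):
            raise ValidationError("n_cancers inconsistent with patients_per_cancer")
        if any(n <= 0 for n in cancers.values()):
            raise ValidationError("patient counts must be positive")
        if self.min_cancers > self.n_cancers:
            raise ValidationError("min_cancers exceeds n_cancers")
        if self.sur_cancers_per_gene < self.min_cancers:
            raise ValidationError("sur_cancers_per_gene below min_cancers")
        if self.sur_cancers_per_gene > self.n_cancers:
            raise ValidationError("sur_cancers_per_gene exceeds n_cancers")
        if self.sur_fold_range[0] <= self.ratio_threshold:
            raise ValidationError(
                "sur_fold_range must lie strictly above the SUR threshold")
        if self.background_fold_range[1] >= self.ratio_threshold:
            raise ValidationError(
                "background_fold_range must lie strictly below the SUR threshold")
        if not (0 <= self.survival_censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_gene_universe(spec: PlantSpec) -> pd.DataFrame:
    """Gene annotation with regulator classes matching the spec proportions.

    Class counts follow largest-remainder rounding of the proportions, and
    classes are assigned to gene ids by a seeded shuffle, so the output is
    deterministic given the seed.
    """
    spec.validate()
    rng = stage_rng(spec.seed, "universe")
    items = sorted(spec.class_proportions.items())
    raw = {c: p * spec.n_genes for c, p in items}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    leftover = spec.n_genes - sum(counts.values())
    by_frac = sorted(items, key=lambda cp: (-(raw[cp[0]] - counts[cp[0]]), cp[0]))
    for c, _ in by_frac[:leftover]:
        counts[c] += 1
    labels = np.repeat([c for c, _ in items], [counts[c] for c, _ in items])
    rng.shuffle(labels)
    ids = _gene_ids(spec.n_genes)
    ann = pd.DataFrame({"symbol": ids, "regulator_class": labels},
                       index=pd.Index(ids, name="gene_id"))
    return ann


def choose_sur_genes(annotation: pd.DataFrame, spec: PlantSpec) -> frozenset:
    """The planted SUR set: as designated, or drawn from the RBP class."""
    if spec.sur_genes is not None:
        missing = set(spec.sur_genes) - set(annotation.index)
        if missing:
            raise ValidationError(f"sur_genes outside universe: {sorted(missing)[:5]}")
        return frozenset(spec.sur_genes)
    # sub-stream 1 of the universe stage: independent of class assignment
    rng = np.random.default_rng([spec.seed, _STAGE["universe"], 1])
    rbps = sorted(annotation.index[annotation["regulator_class"] == "RBP"])
    if len(rbps) < spec.n_sur:
        raise ValidationError("not enough RBP genes to plant the SUR set")
    return frozenset(rng.choice(rbps, size=spec.n_sur, replace=False).tolist())


def generate_healthy_expression(annotation: pd.DataFrame, n_tissues: int,
                                class_location_shift: Mapping[str, float],
                                seed: int | np.random.Generator,
                                base_log_mean: float = np.log(8.0),
                                gene_log_sd: float = 0.8,
                                tissue_log_sd: float = 0.5) -> ExpressionMatrix:
    """Strictly positive log-normal healthy expression, one value per tissue.

    Each gene gets a latent log-level drawn around its class mean (shifted
    by ``class_location_shift``), then per-tissue values scatter around the
    latent level, so class contrasts are present in every tissue while
    genes keep a consistent identity across tissues.
    """
    if n_tissues < 1:
        raise ValidationError("n_tissues must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tissues = list(TISSUES[:n_tissues])
    tissues += [f"tissue_{i}" for i in range(len(tissues) + 1, n_tissues + 1)]
    shifts = annotation["regulator_class"].map(
        lambda c: class_location_shift.get(c, 0.0)).to_numpy(float)
    gene_mu = base_log_mean + shifts + rng.normal(0, gene_log_sd, len(annotation))
    logs = gene_mu[:, None] + rng.normal(0, tissue_log_sd,
                                         (len(annotation), n_tissues))
    values = pd.DataFrame(np.exp(logs), index=annotation.index, columns=tissues)
    return ExpressionMatrix.simple(values, kind="healthy_reference")


def _plant_folds(genes: pd.Index, cancers: list[str], sur_genes: frozenset,
                 spec: PlantSpec, rng: np.random.Generator) -> pd.DataFrame:
    """True per-gene per-cancer fold changes: SUR folds in exactly
    ``sur_cancers_per_gene`` cancers per SUR gene, background elsewhere."""
    lo_b, hi_b = spec.background_fold_range
    folds = pd.DataFrame(rng.uniform(lo_b, hi_b, (len(genes), len(cancers))),
                         index=genes, columns=cancers)
    lo_s, hi_s = spec.sur_fold_range
    for g in sorted(sur_genes):
        chosen = rng.choice(cancers, size=spec.sur_cancers_per_gene,
                            replace=False)
        folds.loc[g, chosen] = rng.uniform(lo_s, hi_s, len(chosen))
    return folds


def generate_cancer_cohorts(healthy: ExpressionMatrix, spec: PlantSpec,
                            sur_genes: frozenset | None = None,
                            gene_noise_cv: pd.Series | None = None,
                            cancer_tissue: Mapping[str, str] | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[dict[str, tuple[ExpressionMatrix, ExpressionMatrix | None]], pd.DataFrame]:
    """Per-cancer tumor cohorts and matched normals around the healthy reference.

    Tumor value = healthy x planted fold x patient noise; matched normal =
    healthy x patient noise.  Noise is multiplicative log-normal with
    median 1 and per-gene CV (all equal to ``spec.patient_noise_cv`` unless
    ``gene_noise_cv`` is supplied).  The first
    ``matched_normal_fraction`` of patients contribute a matched normal;
    the brain cohort contributes none, mirroring a cancer without adjacent
    normal tissue.  Returns ``(cohorts, true_folds)``.
    """
    spec.validate()
    mapping = dict(cancer_tissue if cancer_tissue is not None else CANCER_TISSUE)
    cancers = spec.cancers()
    for c in cancers:
        if c not in mapping:
            raise ValidationError(f"cancer {c!r} has no tissue mapping")
        if mapping[c] not in healthy.sample_ids:
            raise ValidationError(
                f"cancer {c!r} maps to tissue {mapping[c]!r} absent from healthy data")
    if rng is None:
        rng = stage_rng(spec.seed, "cohorts")
    genes = healthy.genes
    if sur_genes is None:
        sur_genes = spec.sur_genes or frozenset()
    if gene_noise_cv is None:
        gene_noise_cv = pd.Series(spec.patient_noise_cv, index=genes)
    sigma = np.array([_noise_sigma(cv) for cv in
                      gene_noise_cv.loc[genes].to_numpy(float)])
    folds = _plant_folds(genes, list(cancers), frozenset(sur_genes), spec, rng)
    cohorts = {}
    for cancer, n_pat in cancers.items():
        h = healthy.values[mapping[cancer]].to_numpy(float)
        noise_t = np.exp(rng.normal(0, 1, (len(genes), n_pat)) * sigma[:, None])
        tumor_vals = h[:, None] * folds[cancer].to_numpy(float)[:, None] * noise_t
        patients = [f"{cancer}_p{i:04d}" for i in range(1, n_pat + 1)]
        tumor = ExpressionMatrix(
            values=pd.DataFrame(tumor_vals, index=genes,
                                columns=[f"{p}_T" for p in patients]),
            samples=pd.DataFrame({"context": cancer, "kind": "tumor",
                                  "patient_id": patients},
                                 index=[f"{p}_T" for p in patients]))
        n_norm = 0 if cancer == "brain_lgg" else int(
            np.ceil(n_pat * spec.matched_normal_fraction))
        if n_norm >= 2:
            noise_n = np.exp(rng.normal(0, 1, (len(genes), n_norm)) * sigma[:, None])
            norm_vals = h[:, None] * noise_n
            norm_pat = patients[:n_norm]
            combined_vals = pd.concat(
                [tumor.values,
                 pd.DataFrame(norm_vals, index=genes,
                              columns=[f"{p}_N" for p in norm_pat])], axis=1)
            normal = ExpressionMatrix(
                values=pd.DataFrame(norm_vals, index=genes,
                                    columns=[f"{p}_N" for p in norm_pat]),
                samples=pd.DataFrame({"context": cancer,
                                      "kind": "matched_normal",
                                      "patient_id": norm_pat},
                                     index=[f"{p}_N" for p in norm_pat]))
            # validate pairing through the combined-sample invariant
            ExpressionMatrix(values=combined_vals,
                             samples=pd.concat([tumor.samples, normal.samples]))
        else:
            normal = None
        cohorts[cancer] = (tumor, normal)
    return cohorts, folds


def generate_ppi_network(annotation: pd.DataFrame, sur_genes,
                         spec: PlantSpec,
                         rng: np.random.Generator | None = None) -> nx.Graph:
    """Heavy-tailed PPI network with an optional dense planted SUR module.

    The background is a preferential-attachment (Barabasi-Albert) graph
    over all genes.  When ``spec.module_density > 0`` the SUR genes are
    additionally wired to a shared hub (the highest-degree SUR gene) and to
    each other with the given edge probability, producing the short
    within-SUR path lengths the downstream comparison recovers.  With
    ``module_density <= 0`` no structure is planted and the SUR label is
    statistically invisible in the wiring.
    """
    sur_genes = frozenset(sur_genes)
    missing = sur_genes - set(annotation.index)
    if missing:
        raise ValidationError(f"sur_genes outside universe: {sorted(missing)[:5]}")
    if rng is None:
        rng = stage_rng(spec.seed, "network")
    n = len(annotation)
    base_seed = int(rng.integers(0, 2 ** 31 - 1))
    g = nx.barabasi_albert_graph(n, min(spec.ba_m, n - 1), seed=base_seed)
    order = annotation.index.to_numpy().copy()  # never mutate the shared index
    rng.shuffle(order)
    g = nx.relabel_nodes(g, dict(enumerate(order.tolist())))
    if spec.module_density > 0 and len(sur_genes) >= 2:
        sur_sorted = sorted(sur_genes)
        hub = max(sur_sorted, key=lambda v: (g.degree(v), v))
        for v in sur_sorted:
            if v != hub:
                g.add_edge(hub, v)
        for i, u in enumerate(sur_sorted):
            for v in sur_sorted[i + 1:]:
                if rng.random() < spec.module_density:
                    g.add_edge(u, v)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def couple_noise_to_degree(degrees: pd.Series, spec: PlantSpec,
                           rng: np.random.Generator | None = None) -> pd.Series:
    """Per-gene patient-noise CVs rank-correlated with network degree.

    Base noise levels are spread as ``patient_noise_cv x U(0.3, 1.7)`` so
    fold-change MADs are distinguishable across genes.  A Gaussian copula
    couples their ranks to the (jittered) degree ranks at the target
    Spearman correlation ``spec.mad_degree_rho``; rho = 0 assigns levels at
    random.
    """
    if rng is None:
        rng = stage_rng(spec.seed, "noise")
    n = len(degrees)
    levels = np.sort(spec.patient_noise_cv * rng.uniform(0.3, 1.7, n))
    rho = float(spec.mad_degree_rho)
    if rho == 0:
        return pd.Series(rng.permutation(levels), index=degrees.index)
    # Pearson rho on normal scores that yields the target Spearman rho
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    jitter = rng.uniform(-0.25, 0.25, n)
    deg_rank = sps.rankdata(degrees.to_numpy(float) + jitter, method="ordinal")
    z_deg = sps.norm.ppf(deg_rank / (n + 1))
    z = r * z_deg + np.sqrt(1 - r ** 2) * rng.normal(0, 1, n)
    level_rank = sps.rankdata(z, method="ordinal").astype(int) - 1
    return pd.Series(levels[level_rank], index=degrees.index)


def generate_complex_catalog(annotation: pd.DataFrame, n_complexes: int,
                             size_distribution: Mapping | None = None,
                             seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Protein-complex catalog with sizes >= 2 drawn from the gene universe.

    ``size_distribution``: ``{"kind": "poisson_shifted", "mean": m}``
    (default, sizes 2 + Poisson(m - 2)) or ``{"kind": "constant", "size": s}``.
    A gene may belong to several complexes.
    """
    if n_complexes < 1:
        raise ValidationError("n_complexes must be >= 1")
    dist = dict(size_distribution or {"kind": "poisson_shifted", "mean": 5.0})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = np.asarray(annotation.index)
    rows = {}
    width = max(4, len(str(n_complexes)))
    for i in range(1, n_complexes + 1):
        if dist["kind"] == "constant":
            size = int(dist["size"])
        elif dist["kind"] == "poisson_shifted":
            size = 2 + int(rng.poisson(max(dist["mean"] - 2.0, 0.0)))
        else:
            raise ValidationError(f"unknown size distribution {dist['kind']!r}")
        size = max(2, min(size, len(genes)))
        members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
        cid = f"C{i:0{width}d}"
        rows[cid] = {"name": f"complex_{i}", "members": members}
    catalog = pd.DataFrame.from_dict(rows, orient="index")
    catalog.index.name = "complex_id"
    return catalog


def generate_survival_cohort(n_patients: int,
                             gene_effects: Mapping[str, float],
                             censor_rate: float,
                             seed: int | np.random.Generator,
                             baseline_hazard: float = 0.1,
                             expression: pd.DataFrame | None = None) -> SurvivalCohort:
    """Survival cohort with exponential event times and planted hazard ratios.

    Each gene's high-expression half (strictly above the cohort median)
    multiplies a patient's hazard by that gene's hazard ratio; effects of
    multiple genes multiply.  Censoring is independent: each patient is
    censored with probability ``censor_rate`` at a uniform fraction of the
    latent event time.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if not (0 <= censor_rate < 1):
        raise ValidationError("censor_rate must be in [0, 1)")
    if any(h <= 0 for h in gene_effects.values()):
        raise ValidationError("hazard ratios must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = sorted(gene_effects)
    patients = [f"sp{i:05d}" for i in range(1, n_patients + 1)]
    if expression is None:
        expression = pd.DataFrame(
            np.exp(rng.normal(np.log(8.0), 1.0, (len(genes), n_patients))),
            index=genes, columns=patients)
    else:
        expression = expression.copy()
        expression.columns = patients[: expression.shape[1]]
        missing = set(genes) - set(expression.index)
        if missing:
            raise ValidationError(f"expression missing genes: {sorted(missing)[:5]}")
    log_hazard = np.full(n_patients, np.log(baseline_hazard))
    for g in genes:
        h = float(gene_effects[g])
        if h == 1.0:
            continue
        vals = expression.loc[g].to_numpy(float)
        high = vals > np.median(vals)
        log_hazard = log_hazard + np.where(high, np.log(h), 0.0)
    latent = rng.exponential(1.0, n_patients) / np.exp(log_hazard)
    censored = rng.random(n_patients) < censor_rate
    times = np.where(censored, latent * rng.uniform(0, 1, n_patients), latent)
    times = np.maximum(times, 1e-12)
    data = pd.DataFrame({"time": times, "event": (~censored).astype(int)},
                        index=pd.Index(patients, name="patient_id"))
    return SurvivalCohort(data=data, expression=expression.loc[genes, patients])


def generate_correlated_survival_cohort(n_patients: int,
                                        gene_effects: Mapping[str, float],
                                        censor_rate: float,
                                        seed: int | np.random.Generator,
                                        baseline_hazard: float = 0.1,
                                        ) -> SurvivalCohort:
    """Survival cohort where hazards flow through one latent patient factor.

    Each patient carries a latent log-hazard z ~ N(0, 1); event times are
    exponential with hazard ``baseline_hazard * exp(z)``.  A gene with
    target hazard ratio h gets expression correlated with z at
    rho = log(h) / (2 * sqrt(2/pi)), which makes the hazard ratio between
    its high- and low-expression halves approximately h while keeping the
    overall hazard spread bounded no matter how many genes carry effects.
    Genes with h = 1 are independent of the latent factor.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if not (0 <= censor_rate < 1):
        raise ValidationError("censor_rate must be in [0, 1)")
    if any(h <= 0 for h in gene_effects.values()):
        raise ValidationError("hazard ratios must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = sorted(gene_effects)
    patients = [f"sp{i:05d}" for i in range(1, n_patients + 1)]
    z = rng.normal(0, 1, n_patients)
    # E[z | above median] - E[z | below] = 2 rho sqrt(2/pi) for bivariate normal
    scale = 2.0 * np.sqrt(2.0 / np.pi)
    rows = np.empty((len(genes), n_patients))
    for gi, g in enumerate(genes):
        rho = np.clip(np.log(float(gene_effects[g])) / scale, -0.99, 0.99)
        latent = rho * z + np.sqrt(1.0 - rho ** 2) * rng.normal(0, 1, n_patients)
        rows[gi] = np.exp(np.log(8.0) + latent)
    expression = pd.DataFrame(rows, index=genes, columns=patients)
    latent_times = rng.exponential(1.0, n_patients) / (baseline_hazard * np.exp(z))
    censored = rng.random(n_patients) < censor_rate
    times = np.where(censored, latent_times * rng.uniform(0, 1, n_patients),
                     latent_times)
    times = np.maximum(times, 1e-12)
    data = pd.DataFrame({"time": times, "event": (~censored).astype(int)},
                        index=pd.Index(patients, name="patient_id"))
    return SurvivalCohort(data=data, expression=expression)


@dataclass
class SyntheticDataset:
    """Bundle of all generated inputs plus the planted ground truth."""

    spec: PlantSpec
    annotation: pd.DataFrame
    sur_genes: frozenset
    healthy: ExpressionMatrix
    cohorts: dict[str, tuple[ExpressionMatrix, ExpressionMatrix | None]]
    true_folds: pd.DataFrame
    network: nx.Graph
    gene_noise_cv: pd.Series
    complexes: pd.DataFrame
    survival: SurvivalCohort
    gene_effects: dict[str, float]
    manifest: dict


def _default_gene_effects(dataset_genes, sur_genes: frozenset,
                          profiles: pd.DataFrame,
                          gene_noise_cv: pd.Series) -> dict[str, float]:
    """Planted hazard ratios for the survival stage.

    SUR genes: HR rises linearly from 1.2 to 3.0 with the rank of their
    mean path length to other SUR genes (the within-group trend the
    path-ranked survival report recovers).  Non-SUR genes: HR falls from
    2.5 to 1.0 with the rank of their planted noise level (low-variability
    genes carry the larger prognostic impact).
    """
    effects: dict[str, float] = {}
    sur_sorted = sorted(sur_genes)
    key = profiles.loc[sur_sorted, "mean_dist_to_sur"]
    ranks = key.rank(method="first")
    for g in sur_sorted:
        frac = (ranks[g] - 1) / max(len(sur_sorted) - 1, 1)
        effects[g] = 1.2 + frac * (3.0 - 1.2)
    non_sur = [g for g in dataset_genes if g not in sur_genes]
    nr = gene_noise_cv.loc[non_sur].rank(method="first")
    for g in non_sur:
        frac = (nr[g] - 1) / max(len(non_sur) - 1, 1)
        effects[g] = 2.5 - frac * 1.5
    return effects


def simulate_all(spec: PlantSpec, n_complexes: int = 200) -> SyntheticDataset:
    """Generate the complete synthetic study for one seed."""
    spec.validate()
    annotation = generate_gene_universe(spec)
    sur = choose_sur_genes(annotation, spec)
    healthy = generate_healthy_expression(
        annotation, spec.n_tissues, spec.class_location_shift,
        stage_rng(spec.seed, "healthy"))
    network = generate_ppi_network(annotation, sur, spec)
    degrees = pd.Series(dict(network.degree()), dtype=float).loc[annotation.index]
    gene_noise_cv = couple_noise_to_degree(degrees, spec)
    cohorts, true_folds = generate_cancer_cohorts(
        healthy, spec, sur_genes=sur, gene_noise_cv=gene_noise_cv)
    catalog = generate_complex_catalog(
        annotation, n_complexes, seed=stage_rng(spec.seed, "complexes"))
    from .network import mean_path_profiles  # local import avoids a cycle
    profiles = mean_path_profiles(network, sur)
    effects = _default_gene_effects(annotation.index, sur, profiles,
                                    gene_noise_cv)
    survival = generate_correlated_survival_cohort(
        spec.survival_n_patients, effects, spec.survival_censor_rate,
        stage_rng(spec.seed, "survival"))
    manifest = {"seed": spec.seed, "n_genes": spec.n_genes,
                "n_cancers": spec.n_cancers,
                "patients_per_cancer": spec.cancers(),
                "n_sur": len(sur),
                "sur_fold_range": list(spec.sur_fold_range),
                "background_fold_range": list(spec.background_fold_range),
                "sur_cancers_per_gene": spec.sur_cancers_per_gene,
                "patient_noise_cv": spec.patient_noise_cv,
                "mad_degree_rho": spec.mad_degree_rho,
                "module_density": spec.module_density,
                "ratio_threshold": spec.ratio_threshold,
                "min_cancers": spec.min_cancers,
                "n_complexes": n_complexes,
                "survival_n_patients": spec.survival_n_patients,
                "survival_censor_rate": spec.survival_censor_rate}
    return SyntheticDataset(spec=spec, annotation=annotation, sur_genes=sur,
                            healthy=healthy, cohorts=cohorts,
                            true_folds=true_folds, network=network,
                            gene_noise_cv=gene_noise_cv, complexes=catalog,
                            survival=survival, gene_effects=effects,
                            manifest=manifest)
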