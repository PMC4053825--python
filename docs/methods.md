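# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations of the statistical procedures.

## Fold-change model and SUR calling

Per-patient fold changes are computed on the plain ratio scale,
`(tumor + ε) / (healthy + ε)`, with a pseudocount ε defaulting to 0.01 RPKM.
ε exists only to keep ratios finite when a healthy reference is zero; it is
configurable and may be set to 0 when the reference is strictly positive.
Each gene × cancer cell is summarized by the median of the per-patient
ratios (robust to outlier patients), its log2, and the raw median absolute
deviation of the ratios. The MAD is deliberately unscaled — no 1.4826
normal-consistency factor — because it is used as an ordinal variability
measure (quartile classes), never as a σ estimate.

The strongly-upregulated (SUR) criterion is: median ratio ≥ 9 in at least 6
of the 9 profiled cancers. Two conventions are fixed and tested:

* the threshold applies to the **plain ratio**, not its logarithm (a config
  switch `scale="log2"` applies it to the log2 median ratio instead); a
  ninefold change is a biologically strong but attainable signal, whereas a
  log-ratio of 9 (512-fold) would be extreme;
* the comparison is **inclusive** (≥ 9, ≥ 6 cancers), so a gene at exactly
  ninefold in exactly six cancers is SUR.

SUR calling is monotone in both thresholds (property-tested): raising either
can only shrink the called set.

Variability classes use linear-interpolation percentiles with strict
inequalities at both bounds: MAD > 75th percentile → high, < 25th → low,
everything else (including exact ties with a bound) → medium. On tie-free
vectors of 4k genes this yields a 25/50/25 partition within one gene.

Tumor-matched testing is a **paired** two-sided t-test on
log2(tumor + ε) − log2(normal + ε), restricted to patients contributing both
samples; a cancer with fewer than two pairs is untestable and excluded from
the per-gene count of significant cancers. Degenerate conventions: all-zero
differences give p = 1, constant non-zero differences give p = 0.

Cancer similarity uses average-linkage agglomerative clustering on
1 − Pearson correlation of the per-gene log2 median ratios; zero-variance
columns are rejected by name because their correlation is undefined.

## Rank-based tests

`rank_sum_test` is the two-sided two-sample Mann–Whitney test. For pooled
sample sizes ≤ 12 it enumerates **all** C(n+m, n) rank assignments of the
pooled (possibly tied) values and reports
P(|U − nm/2| ≥ |u_obs − nm/2|) under that permutation null, which is
symmetric in the groups; the null distribution is cached per pooled
multiset. Larger samples use the normal approximation with midranks, tie
correction and continuity correction. Kruskal–Wallis uses the tie-corrected
H with a χ²(k−1) reference; the all-values-identical case returns H = 0,
p = 1 by construction. Hypergeometric enrichment is the upper tail
P(X ≥ k) — over-representation only.

## Network conventions

The PPI graph is simple and undirected; edge-list readers upper-case
symbols, match them exactly (no alias resolution), and drop self-loops and
duplicate edges with logged counts.

Normalizations: degree/(n−1); closeness with the Wasserman–Faust component
correction (reachable count over distance sum, scaled by the reachable
fraction), so values stay in [0, 1] on disconnected graphs; betweenness
× 2/((n−1)(n−2)) (undirected pairs counted once); local clustering
coefficient. Betweenness is reported as NaN with a warning below n = 3.

Within-group path-length distributions count each unordered pair once.
**Unreachable pairs are excluded and counted**, not imputed with a sentinel
distance; per-node mean distances to a group likewise average over reachable
targets only (self always excluded) and are NaN with a zero reachable count
when no target is reachable. An optional restriction to the largest
connected component is available in the readers' callers but off by
default, keeping the default faithful to "every pair".

Path-length rankings break ties lexicographically by gene symbol, and the
random intermediate selection draws from its own seeded generator, so the
shortest/intermediate/longest panels are disjoint and reproducible.

### Caveat: dependence of pairwise distances

The comparison of within-SUR vs within-non-SUR path-length distributions
follows the field's convention of applying a rank-sum test to the pooled
pairwise distances. Pairs sharing an endpoint are positively dependent (a
hub in the group shifts all of its incident pairs), so the independent-
sample null understates the variance of the rank statistic and the test is
**anticonservative under the null**: with 25-gene groups on 500-node
preferential-attachment graphs the acceptance script measures a null
rejection rate far above the nominal α (reported as
`module_null_rejection_rate`). The planted-module contrast itself is
enormous and unaffected, but the nominal p-value of this particular
comparison should be read as descriptive, not calibrated. A calibrated
alternative would permute group labels at the node level and recompute the
statistic; that is out of scope here and the faithful test is kept.

Two-sample KS tests on integer degree distributions are conservative under
heavy ties (measured null rejection ≈ 0.01 at α = 0.05,
`mad_degree_null_rejection_rate`); their type-I error is controlled, which
is the property the null check asserts.

## Survival engine

The Kaplan–Meier estimator is the product-limit formula over distinct event
times; patients censored exactly at an event time are counted at risk at
that time. The log-rank test is the standard χ² with one degree of freedom
using the hypergeometric variance at each event time; the hazard-ratio
estimate is (O_a/E_a)/(O_b/E_b) from the same bookkeeping, which inverts
exactly under group relabeling. Expression dichotomization splits at the
median with ties assigned to the low group; all-identical expression admits
no split and excludes the gene with a flag. Prognostic impact is −log10 of
the log-rank p; p-values of exactly zero are floored at the smallest
positive double before the transform. The O/E ratio mildly underestimates
large hazard ratios (median ≈ 2.6 at a planted HR of 3 with 20% censoring),
a known property of this estimator, and the recovery check brackets it
accordingly.

## The synthetic-data generator

All generators are deterministic given the study seed; each stage draws
from `default_rng([seed, stage_id])`, so adding a stage never perturbs
earlier stages' draws.

* **Gene universe**: 1,000 genes split RBP/TF/miRNA/lncRNA/other at
  0.25/0.12/0.05/0.18/0.40 by largest-remainder rounding — a desk-scale
  caricature of the human regulator-class inventory with the focal class
  well represented.
* **Healthy expression** is log-normal per class: a per-gene latent
  log-level around its class mean (gene SD 0.8) plus per-tissue scatter
  (SD 0.5), giving strictly positive, heavy-right-tailed, RPKM-like values
  with consistent gene identity across the 16 tissues. The planted RBP
  location shift is log 4 (miRNA/lncRNA shifted down log 2), large enough
  that the class contrast is unambiguous in every tissue at these sizes.
* **Cancer cohorts**: 9 cancers × 50 patients against 8 matched tissues
  (two lung cancers share one tissue). Tumor value = healthy × planted fold
  × patient noise; matched normal = healthy × noise. Noise is multiplicative
  log-normal with **median 1** (so the planted fold is the expected median
  ratio) and per-gene CV spread as 0.3 × U(0.3, 1.7). The 25 SUR genes are
  drawn from the RBP class and receive folds U(10, 50) in exactly 7 of the
  9 cancers; all other gene × cancer folds are U(0.5, 3). Both ranges are
  validated to straddle the ninefold threshold strictly, which is what makes
  exact recovery a meaningful check. Half the patients contribute matched
  normals; the brain cohort contributes none, mirroring a cancer without
  adjacent normal tissue.
* **PPI network**: a Barabási–Albert graph (m = 3) over all genes — heavy-
  tailed degrees — plus a planted module: every SUR gene is wired to the
  highest-degree SUR hub and SUR pairs are connected with probability 0.3.
  Setting the module density to 0 removes all planted wiring.
* **MAD–degree coupling**: per-gene noise CVs are rank-coupled to (jittered)
  network degree through a Gaussian copula at Pearson 2·sin(πρ/6), the
  value whose normal-scores correlation yields Spearman ρ (target 0.6 in
  the study configuration); ρ = 0 assigns levels at random.
* **Complex catalog**: 200 complexes with sizes 2 + Poisson(3), members
  drawn uniformly — deliberately *unrelated* to SUR status, so the complex
  stage acts as a negative control.
* **Survival**: two generators. The single/few-gene generator gives each
  gene's high-expression half a multiplicative hazard (used for the
  calibration and power studies). The full-study generator routes all
  effects through one latent patient log-hazard z ~ N(0,1): event times are
  exponential with hazard 0.1·e^z, and a gene with target HR h gets
  expression correlated with z at ρ = log h / (2√(2/π)), which makes the
  median-split hazard ratio ≈ h while keeping the hazard spread bounded no
  matter how many genes carry effects (independent multiplicative effects
  across 1,000 genes would drown every signal in frailty noise). Planted
  trends: SUR genes' HR rises 1.2 → 3.0 with their mean path length to the
  other SUR genes; non-SUR genes' HR falls 2.5 → 1.0 with their planted
  noise rank. Censoring is independent with probability 0.2, at a uniform
  fraction of the latent event time.

### What passing tests do and do not show

The generator emulates the *shapes* and *planted contrasts* of a pan-cancer
study, not real data: there are no batch effects, no library-size or
GC biases, no correlated gene modules beyond the planted ones, no
copy-number or mutation structure, dense matrices with no missingness, and
exact symbol identity across all artifacts. Recovery of planted signals
demonstrates that the estimators and thresholds do what they claim under
the stated noise model; it says nothing about robustness to the
harmonization, confounding and annotation problems of real cohorts.

## Problem sizes

The default study (1,000 genes, 9 × 50 patients, 300 survival patients,
200 complexes) runs end-to-end in seconds and is used everywhere — unit
tests, the analysis drivers and the acceptance script. Calibration checks
use 200 seeds (null rejection rates) and 2,000 replicates (log-rank type-I
error at n = 200); oracle checks use 100 random graphs of up to 50 nodes
and exhaustive enumeration up to universes of 12. These sizes were chosen
so each contrast is decisively powered at desk scale.
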