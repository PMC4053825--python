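# rbpscape

A tested, reusable implementation of a pan-cancer dysregulation pipeline for
RNA-binding proteins (RBPs), for computational biologists who want the full
analysis chain — expression profiling, fold-change classification, interaction
network analysis, protein-complex statistics and survival profiling — as
importable, seedable library code rather than a one-off collection of scripts.
Because the original study's inputs (a healthy-tissue RNA-seq reference,
per-cancer tumor cohorts, a curated PPI network, a complex catalog and a
survival resource) are large external downloads, the package ships a
first-class synthetic-data generator that emulates all five inputs with
*planted* signals, so every stage is validated by parameter recovery.

## The analysis

1. **Healthy-tissue profiling.** Per tissue, RPKM distributions of RBPs are
   compared against transcription factors, miRNAs, lncRNAs and other genes
   with the two-sample rank-sum (Wilcoxon/Mann–Whitney) test and across all
   classes with Kruskal–Wallis. The rank-sum test enumerates all rank
   assignments exactly for pooled samples ≤ 12 (tie-aware) and otherwise uses
   the normal approximation with tie and continuity corrections.
2. **Strongly-upregulated (SUR) calling.** For gene *g* and cancer *c* with
   healthy reference *h_g* and patient tumor values *x_{gcp}*, the per-patient
   fold change is *r_{gcp} = (x_{gcp} + ε)/(h_g + ε)* (ε = 0.01 RPKM). Each
   gene × cancer is summarized by median ratio *m_{gc}*, log2 *m_{gc}*, and
   the raw MAD of the *r_{gcp}*. A gene is SUR iff *m_{gc}* ≥ 9 in at least 6
   of the 9 cancers. Upper-quartile membership, RBP enrichment (upper-tail
   hypergeometric), paired tumor-vs-matched-normal t-tests on
   log2 differences, MAD quartile variability classes (low < 25th pct <
   medium < 75th pct < high) and average-linkage clustering of cancers on
   1 − Pearson distance complete the stage.
3. **Network analysis.** On an undirected simple PPI graph: normalized
   degree, closeness (Wasserman–Faust), betweenness and clustering
   coefficients; distributions of shortest-path lengths within the SUR and
   within the non-SUR group; per-gene mean distances to each group; selection
   of the 5 shortest / 5 longest / 5 random intermediate genes by mean path
   length; and two-sample KS comparisons of interaction counts across
   variability classes.
4. **Complex statistics.** Per-gene complex membership counts and mean
   complex sizes, compared between SUR and non-SUR genes (rank-sum), with
   Spearman correlations against fold change.
5. **Survival.** An in-house Kaplan–Meier / log-rank engine: patients are
   split at the median expression of each gene (ties to low), the groups are
   compared by the log-rank χ² (1 df), prognostic impact is −log10 *p* with
   an observed/expected hazard ratio (O_a/E_a)/(O_b/E_b), and impact
   distributions are compared across SUR status and variability classes (KS).

## Worked example

The numbered drivers under `analysis/` run the whole study on one synthetic
dataset (seed 11; 1,000 genes, 9 cancers × 50 patients, 25 planted SUR genes
with true folds 10–50 in 7 of 9 cancers, MAD–degree coupling 0.6):

```sh
cd analysis
python 01_simulate.py && python 03_dysregulation.py && python 04_network.py
```

prints (abridged):

```
planted SUR genes: 25 (folds (10.0, 50.0) in 7 of 9 cancers)
SUR genes called: 25 (planted 25; exact recovery: True)
RBPs in upper fold-change quartile: 75 of 250 (hypergeometric p = 0.0225)
variability classes (breast): {'medium': 500, 'low': 250, 'high': 250}
within-SUR median path 2.0 vs within-non-SUR 4.0 (rank-sum p = 1.77e-212)
degree by variability low_vs_high: medians 3 vs 6, KS p = 4.45e-26
```

Reading: the fold-change classifier recovers exactly the 25 planted SUR
genes; the dense planted module halves within-SUR path lengths relative to
the non-SUR background; and the planted coupling between expression
variability and connectivity doubles the median degree of high-variability
genes. `python 06_survival.py` then shows the planted survival structure
(path length vs prognostic impact, Spearman ρ = 0.85; low- vs
high-variability prognosis, KS p = 3.5 × 10⁻⁴⁶). The same pipeline is
available end-to-end as `rbpscape run-all --seed 11 --out results/run`.

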