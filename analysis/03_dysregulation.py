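#!/usr/bin/env python
"""Stage 2: fold-change profiling, SUR calling and variability classes.

Computes per-patient tumor/healthy fold changes for all nine cancers,
summarizes each gene x cancer by the median ratio and its MAD, calls
strongly-upregulated (SUR) genes (median ratio >= 9 in >= 6 cancers),
tests RBP enrichment in the upper quartile, runs the tumor-matched paired
t-tests, classifies breast-cohort variability and clusters the cancers by
their log2 fold-change profiles.
"""

import pandas as pd

from _study import dataset, outdir
from rbpscape import dysreg
from rbpscape.synth import CANCER_TISSUE


def main() -> None:
    d = dataset()
    out = outdir("tables")
    ratios = {c: dysreg.patient_fold_changes(
        t, d.healthy.values[CANCER_TISSUE[c]])
        for c, (t, _n) in d.cohorts.items()}
    summary = dysreg.summarize_fold_changes(ratios)
    call = dysreg.classify_sur(summary)
    call.table.to_csv(out / "sur_calls.tsv", sep="\t")
    exact = call.sur_genes == d.sur_genes
    print(f"SUR genes called: {len(call.sur_genes)} "
          f"(planted {len(d.sur_genes)}; exact recovery: {exact})")

    uq = dysreg.upper_quartile_flags(summary)
    rbp = d.annotation["regulator_class"] == "RBP"
    enr = dysreg.hypergeometric_enrichment(
        k=int((uq & rbp).sum()), K=int(uq.sum()),
        n=int(rbp.sum()), N=len(uq))
    print(f"RBPs in upper fold-change quartile: {int((uq & rbp).sum())} of "
          f"{int(uq.sum())} (hypergeometric p = {enr.p_value:.3g})")

    pvals, counts = dysreg.tumor_matched_tests(d.cohorts)
    sur_counts = counts.loc[sorted(call.sur_genes)]
    print(f"tumor-matched tests: all SUR genes significant in >= "
          f"{int(sur_counts.min())} of {pvals.notna().any().sum()} testable "
          f"cancers at p < 0.001")

    vc = dysreg.classify_variability(summary, "breast_ca")
    pd.DataFrame({"mad_ratio": vc.mad, "variability": vc.label}).to_csv(
        out / "variability_classes.tsv", sep="\t")
    print("variability classes (breast):",
          vc.label.value_counts().to_dict())

    z, labels = dysreg.cluster_cancers(summary.log2_median_ratio)
    nwk = dysreg.linkage_to_newick(z, labels)
    (out / "cancer_dendrogram.newick").write_text(nwk + "\n")
    first = {labels[int(z[0, 0])] if z[0, 0] < len(labels) else "cluster",
             labels[int(z[0, 1])] if z[0, 1] < len(labels) else "cluster"}
    print(f"cancer clustering: first merge = {sorted(first)}")
    summary.median_ratio.to_csv(out / "median_fold_changes.tsv", sep="\t")
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
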