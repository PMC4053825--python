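#!/usr/bin/env python
"""Stage 4: protein-complex membership of SUR vs non-SUR genes.

The complex catalog is generated without reference to the SUR set, so the
expectation mirrors a negative control: no membership-count or mean-size
difference between the groups, and no correlation with fold change.
"""

import pandas as pd

from _study import dataset, outdir
from rbpscape import complexes as cx, dysreg
from rbpscape.synth import CANCER_TISSUE


def main() -> None:
    d = dataset()
    out = outdir("tables")
    sur = d.sur_genes
    non_sur = set(d.annotation.index) - sur
    sur_stats = cx.complex_membership_stats(d.complexes, sur)
    non_stats = cx.complex_membership_stats(d.complexes, non_sur)
    pd.concat([sur_stats.table.assign(group="SUR"),
               non_stats.table.assign(group="non-SUR")]).to_csv(
        out / "complex_stats.tsv", sep="\t")
    n_sur_members = int((sur_stats.table["n_complexes"] > 0).sum())
    n_non_members = int((non_stats.table["n_complexes"] > 0).sum())
    print(f"complex members: {n_sur_members} SUR, {n_non_members} non-SUR")

    ratios = {c: dysreg.patient_fold_changes(
        t, d.healthy.values[CANCER_TISSUE[c]])
        for c, (t, _n) in d.cohorts.items()}
    log2fc = dysreg.summarize_fold_changes(ratios).log2_median_ratio.median(axis=1)
    res = cx.compare_complex_stats(sur_stats, non_stats, log2fc)
    for name, r in res.items():
        print(f"{name}: statistic {r.statistic:.3g}, p = {r.p_value:.3g}")
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
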