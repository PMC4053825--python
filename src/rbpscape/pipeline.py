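"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` drives: (1) healthy-tissue class profiling, (2)
fold-change summarization, SUR calling, enrichment, tumor-matched tests,
variability classes and cancer clustering, (3) PPI metrics, group path
distributions and path-ranked selections, (4) complex membership
comparisons, (5) survival profiling and prognosis comparisons — all on a
synthetic study generated from one :class:`~rbpscape.synth.PlantSpec`.

Every output TSV carries a header comment with the configuration hash and
seed; reruns with the same configuration are byte-identical.  A stage
failure aborts the run, removes the files written so far, and re-raises
with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexes as cx
from . import dysreg, io, network as net, profiling, survival as surv
from .datatypes import ValidationError
from .synth import CANCER_TISSUE, PlantSpec, SyntheticDataset, simulate_all

log = logging.getLogger(__name__)

VARIABILITY_REFERENCE_CANCER = "breast_ca"  # largest default cohort


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run."""

    plant: PlantSpec = field(default_factory=PlantSpec)
    ratio_threshold: float = 9.0
    min_cancers: int = 6
    pseudocount: float = 0.01
    q_low: float = 25.0
    q_high: float = 75.0
    p_cut: float = 0.001
    selection_k: int = 5
    n_complexes: int = 200
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self) -> None:
        # one seed drives both the generators and the analysis stages
        if self.plant.seed != self.seed:
            self.plant = replace(self.plant, seed=self.seed)

    def validate(self) -> None:
        if self.ratio_threshold <= 0 or self.pseudocount < 0:
            raise ValidationError("thresholds must be positive")
        if not (0 <= self.q_low < self.q_high <= 100):
            raise ValidationError("variability percentiles must be ordered")
        if self.min_cancers > self.plant.n_cancers:
            raise ValidationError("min_cancers exceeds the number of cancers")
        if self.selection_k < 1:
            raise ValidationError("selection_k must be >= 1")
        self.plant.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plant"]["sur_genes"] = (sorted(self.plant.sur_genes)
                                   if self.plant.sur_genes else None)
        for key in ("class_proportions", "class_location_shift"):
            d["plant"][key] = dict(sorted(d["plant"][key].items()))
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        plant = dict(d.pop("plant", {}))
        if plant.get("sur_genes"):
            plant["sur_genes"] = frozenset(plant["sur_genes"])
        for key in ("sur_fold_range", "background_fold_range"):
            if key in plant:
                plant[key] = tuple(plant[key])
        known = {f.name for f in fields(PlantSpec)}
        unknown = set(plant) - known
        if unknown:
            raise ValidationError(f"unknown plant option(s): {sorted(unknown)}")
        cfg_known = {f.name for f in fields(RunConfig)}
        unknown = set(d) - cfg_known
        if unknown:
            raise ValidationError(f"unknown config option(s): {sorted(unknown)}")
        return RunConfig(plant=PlantSpec(**plant), **d)

    def config_hash(self) -> str:
        # the hash covers the scientific configuration, not the output path
        d = self.to_dict()
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _OutputTracker:
    """Records written files so a failed run can clean up after itself."""

    def __init__(self, outdir: Path, header: list[str]):
        self.outdir = outdir
        self.header = header
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def tsv(self, frame: pd.DataFrame, name: str, index_label: str) -> None:
        io._write_tsv(frame, self.path(name), index_label=index_label,
                      header_lines=self.header)

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _test_results_frame(results, labels=None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "label": labels[i] if labels else r.extra.get("pair", str(i)),
            "method": r.method, "statistic": r.statistic,
            "p_value": r.p_value,
            "n_a": r.n_per_group[0],
            "n_b": r.n_per_group[1] if len(r.n_per_group) > 1 else np.nan,
            **{k: v for k, v in r.extra.items() if np.isscalar(v)},
        })
    return pd.DataFrame(rows).set_index("label")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the report directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"rbpscape config_hash={config.config_hash()} seed={config.seed}"]
    out = _OutputTracker(outdir, header)
    stage = "simulate"
    try:
        data = simulate_all(config.plant, n_complexes=config.n_complexes)
        _write_inputs(data, out)

        stage = "profile"
        contrasts = [("RBP", c) for c in ("TF", "miRNA", "lncRNA", "other")
                     if c in set(data.annotation["regulator_class"])]
        prof = profiling.compare_classes_per_tissue(
            data.healthy, data.annotation, contrasts)
        out.tsv(prof.set_index("tissue"), "class_profiling.tsv", "tissue")

        stage = "dysreg"
        ratios = {}
        for cancer, (tumor, _normal) in data.cohorts.items():
            healthy_ref = data.healthy.values[CANCER_TISSUE[cancer]]
            ratios[cancer] = dysreg.patient_fold_changes(
                tumor, healthy_ref, pseudocount=config.pseudocount)
        summary = dysreg.summarize_fold_changes(ratios)
        fc = pd.concat({"median_ratio": summary.median_ratio,
                        "log2_median_ratio": summary.log2_median_ratio,
                        "mad_ratio": summary.mad_ratio}, axis=1)
        fc.columns = [f"{a}.{b}" for a, b in fc.columns]
        out.tsv(fc, "fold_change_summary.tsv", "gene_id")
        call = dysreg.classify_sur(summary, config.ratio_threshold,
                                   config.min_cancers)
        out.tsv(call.table, "sur_calls.tsv", "gene_id")
        uq = dysreg.upper_quartile_flags(summary)
        rbp = data.annotation["regulator_class"] == "RBP"
        enrich = dysreg.hypergeometric_enrichment(
            k=int((uq & rbp).sum()), K=int(uq.sum()),
            n=int(rbp.sum()), N=len(uq))
        sur_prop = dysreg.hypergeometric_enrichment(
            k=int((call.table["is_sur"] & rbp).sum()),
            K=int(call.table["is_sur"].sum()) or 0,
            n=int(rbp.sum()), N=len(call.table))
        out.tsv(_test_results_frame(
            [enrich, sur_prop],
            labels=["rbp_in_upper_quartile", "rbp_among_sur"]),
            "enrichment.tsv", "label")
        pvals, counts = dysreg.tumor_matched_tests(
            data.cohorts, pseudocount=config.pseudocount, p_cut=config.p_cut)
        matched = pvals.copy()
        matched["n_cancers_significant"] = counts
        out.tsv(matched, "tumor_matched_tests.tsv", "gene_id")
        varclass = dysreg.classify_variability(
            summary, VARIABILITY_REFERENCE_CANCER, config.q_low, config.q_high)
        out.tsv(pd.DataFrame({"mad_ratio": varclass.mad,
                              "variability": varclass.label}),
                "variability_classes.tsv", "gene_id")
        z, labels = dysreg.cluster_cancers(summary.log2_median_ratio)
        newick = dysreg.linkage_to_newick(z, labels)
        with open(out.path("cancer_dendrogram.newick"), "w") as fh:
            fh.write(f"# {header[0]}\n{newick}\n")

        stage = "network"
        metrics = net.compute_node_metrics(data.network)
        out.tsv(metrics, "node_metrics.tsv", "gene")
        sur_set = call.sur_genes
        non_sur = set(data.annotation.index) - sur_set
        d_sur, un_sur = net.group_pairwise_distances(data.network, sur_set)
        d_non, un_non = net.group_pairwise_distances(data.network, non_sur)
        dist_cmp = net.compare_distance_distributions(d_sur, d_non)
        dist_cmp.extra["unreachable_sur_pairs"] = un_sur
        dist_cmp.extra["unreachable_nonsur_pairs"] = un_non
        out.tsv(_test_results_frame([dist_cmp], labels=["sur_vs_nonsur_paths"]),
                "distance_comparison.tsv", "label")
        profiles = net.mean_path_profiles(data.network, sur_set)
        out.tsv(profiles, "group_path_profiles.tsv", "gene")
        sur_profiles = profiles[profiles["is_sur"]]
        selection = net.rank_and_select(sur_profiles, "mean_dist_to_sur",
                                        k=config.selection_k, seed=config.seed)
        sel_rows = [{"group": grp, "gene": g}
                    for grp in ("shortest", "intermediate", "longest")
                    for g in selection[grp]]
        out.tsv(pd.DataFrame(sel_rows).set_index("gene"),
                "path_selection.tsv", "gene")
        deg_var = net.degree_vs_variability(varclass, metrics)
        out.tsv(_test_results_frame(deg_var), "degree_vs_variability.tsv",
                "label")

        stage = "complexes"
        sur_stats = cx.complex_membership_stats(data.complexes, sur_set)
        non_stats = cx.complex_membership_stats(data.complexes, non_sur)
        both = pd.concat([sur_stats.table.assign(group="SUR"),
                          non_stats.table.assign(group="non-SUR")])
        out.tsv(both, "complex_stats.tsv", "gene")
        log2fc = summary.log2_median_ratio.median(axis=1)
        cmp_res = cx.compare_complex_stats(sur_stats, non_stats, log2fc)
        out.tsv(_test_results_frame(list(cmp_res.values()),
                                    labels=list(cmp_res)),
                "complex_comparison.tsv", "label")

        stage = "survival"
        prog, excluded = surv.prognostic_profiles(data.survival)
        out.tsv(prog, "prognostic_profiles.tsv", "gene")
        report, corrs = surv.path_length_survival_report(
            selection, profiles["mean_dist_to_sur"], prog)
        out.tsv(report.set_index("gene"), "path_survival_report.tsv", "gene")
        out.tsv(_test_results_frame(list(corrs.values()), labels=list(corrs)),
                "path_survival_correlations.tsv", "label")
        partition = pd.Series(
            np.where(call.table["is_sur"], "SUR", "non-SUR"),
            index=call.table.index)
        cmp_sur = surv.compare_prognosis_distributions(prog["neg_log_p"],
                                                       partition)
        cmp_var = surv.compare_prognosis_distributions(prog["neg_log_p"],
                                                       varclass.label)
        out.tsv(_test_results_frame(cmp_sur + cmp_var),
                "prognosis_comparisons.tsv", "label")

        cfg_dict = config.to_dict()
        cfg_dict.pop("outdir", None)
        manifest = {"config": cfg_dict,
                    "config_hash": config.config_hash(),
                    "excluded_survival_genes": sorted(excluded)}
        io.write_config(manifest, out.path("manifest.yaml"))
    except Exception as exc:
        out.cleanup()
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def _write_inputs(data: SyntheticDataset, out: _OutputTracker) -> None:
    """Persist the generated inputs in the same formats the readers accept."""
    io.write_annotation(data.annotation, out.path("annotation.tsv"),
                        header_lines=out.header)
    io.write_expression(data.healthy, out.path("healthy_expression.tsv"),
                        samples_path=out.path("healthy_samples.tsv"),
                        header_lines=out.header)
    for cancer, (tumor, normal) in data.cohorts.items():
        io.write_expression(tumor, out.path(f"tumor_{cancer}.tsv"),
                            samples_path=out.path(f"tumor_{cancer}_samples.tsv"),
                            header_lines=out.header)
        if normal is not None:
            io.write_expression(
                normal, out.path(f"normal_{cancer}.tsv"),
                samples_path=out.path(f"normal_{cancer}_samples.tsv"),
                header_lines=out.header)
    io.write_edge_list(data.network, out.path("ppi_edges.tsv"),
                       header_lines=out.header)
    io.write_complexes(data.complexes, out.path("complex_catalog.tsv"),
                       header_lines=out.header)
    io.write_survival(data.survival, out.path("survival_cohort.tsv"),
                      header_lines=out.header)
    io.write_config(data.manifest, out.path("plant_manifest.yaml"))
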