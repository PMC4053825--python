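#!/usr/bin/env python
"""Generate the synthetic study inputs and write them to results/data.

Emulates the shape of a pan-cancer expression study: a 16-tissue healthy
reference, nine tumor cohorts (two lung cancers sharing one healthy
tissue), a PPI network with a dense module wiring the 25 planted SUR
genes, a 200-entry protein-complex catalog and a 300-patient survival
cohort with expression-linked hazards.
"""

from _study import dataset, outdir, study_spec
from rbpscape.pipeline import RunConfig, _OutputTracker, _write_inputs


def main() -> None:
    d = dataset()
    out = outdir("data")
    cfg = RunConfig(plant=study_spec(), seed=study_spec().seed,
                    outdir=str(out))
    tracker = _OutputTracker(
        out, [f"rbpscape config_hash={cfg.config_hash()} seed={cfg.seed}"])
    _write_inputs(d, tracker)
    classes = d.annotation["regulator_class"].value_counts().to_dict()
    print(f"gene universe: {len(d.annotation)} genes {classes}")
    print(f"planted SUR genes: {len(d.sur_genes)} "
          f"(folds {d.spec.sur_fold_range} in {d.spec.sur_cancers_per_gene} "
          f"of {d.spec.n_cancers} cancers)")
    print(f"PPI network: {d.network.number_of_nodes()} nodes, "
          f"{d.network.number_of_edges()} edges")
    print(f"survival cohort: {d.survival.data.shape[0]} patients, "
          f"censoring rate {1 - d.survival.data['event'].mean():.2f}")
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
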