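"""Shared study definition for the numbered analysis drivers.

One desk-scale synthetic study (seed 11): 1,000 genes, 9 cancers x 50
patients, 25 planted SUR genes, MAD-degree coupling 0.6.  Every driver
derives the identical dataset from this spec, so the scripts can be run
independently and in any order.
"""

from functools import lru_cache
from pathlib import Path

from rbpscape.synth import PlantSpec, simulate_all

STUDY_SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_spec() -> PlantSpec:
    return PlantSpec(seed=STUDY_SEED, mad_degree_rho=0.6)


@lru_cache(maxsize=1)
def dataset():
    return simulate_all(study_spec(), n_complexes=200)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
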