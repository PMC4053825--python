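import numpy as np
import pandas as pd
import pytest

from rbpscape.datatypes import ExpressionMatrix, FoldChangeSummary
from rbpscape.synth import PlantSpec, simulate_all


def make_summary(median_ratio: pd.DataFrame,
                 mad_ratio: pd.DataFrame | None = None) -> FoldChangeSummary:
    """Build a FoldChangeSummary directly from per-cancer medians (test helper)."""
    if mad_ratio is None:
        mad_ratio = median_ratio * 0.0
    return FoldChangeSummary(
        patient_ratios={c: median_ratio[[c]] for c in median_ratio.columns},
        median_ratio=median_ratio,
        log2_median_ratio=np.log2(median_ratio),
        mad_ratio=mad_ratio,
        n_patients=pd.Series(1, index=median_ratio.columns),
    )


@pytest.fixture(scope="session")
def small_spec() -> PlantSpec:
    """Desk-scale-but-small study: 150 genes, 9 cancers x 10 patients."""
    return PlantSpec(n_genes=150, n_sur=8, seed=7,
                     patients_per_cancer={c: 10 for c in (
                         "breast_ca", "brain_lgg", "colon_ad", "kidney_rcc",
                         "liver_hcc", "lung_ad", "lung_sq", "prostate_ad",
                         "thyroid_ca")},
                     survival_n_patients=60)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_all(small_spec, n_complexes=40)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
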