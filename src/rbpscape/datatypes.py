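"""Shared in-memory containers for the pipeline.

Expression matrices are dense genes x samples DataFrames of non-negative
RPKM-like values; sample metadata (tissue/cancer context, sample kind,
patient id) rides alongside as a second DataFrame.  Statistical outputs are
carried as :class:`TestResult` records so every stage reports its method,
statistic, p-value and group sizes uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

REGULATOR_CLASSES = ("RBP", "TF", "miRNA", "lncRNA", "other")

SAMPLE_KINDS = ("healthy_reference", "tumor", "matched_normal")


class ValidationError(ValueError):
    """An input violates a documented contract (bad counts, vocabulary, ...)."""


class ParseError(ValueError):
    """An on-disk artifact could not be parsed; message names the offending cell."""


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``extra`` carries method-specific quantities (group medians, hazard
    ratios, KS statistic components) without widening the common surface.
    """

    method: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``samples`` is indexed by sample id with columns ``context`` (tissue or
    cancer label), ``kind`` (one of SAMPLE_KINDS) and ``patient_id``
    (empty string where not applicable).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            raise ValidationError("duplicate gene ids in expression matrix")
        if not v.columns.is_unique:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValidationError("expression matrix contains negative values")
        if list(self.samples.index) != list(v.columns):
            raise ValidationError("sample metadata does not match matrix columns")
        bad = set(self.samples["kind"]) - set(SAMPLE_KINDS)
        if bad:
            raise ValidationError(f"unknown sample kind(s): {sorted(bad)}")
        # matched normals must pair with a tumor sample of the same context
        meta = self.samples
        norm = meta[meta["kind"] == "matched_normal"]
        tum = meta[meta["kind"] == "tumor"]
        if len(norm) and len(tum):
            keys = set(zip(tum["context"], tum["patient_id"]))
            orphans = [
                s for s, r in norm.iterrows()
                if (r["context"], r["patient_id"]) not in keys
            ]
            if orphans:
                raise ValidationError(
                    f"matched_normal samples without tumor pair: {orphans[:5]}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @staticmethod
    def simple(values: pd.DataFrame, context: Mapping[str, str] | str = "",
               kind: str = "healthy_reference") -> "ExpressionMatrix":
        """Wrap a bare matrix; context defaults to the column name itself."""
        if isinstance(context, str) and context == "":
            ctx = list(values.columns)
        elif isinstance(context, str):
            ctx = [context] * values.shape[1]
        else:
            ctx = [context[c] for c in values.columns]
        meta = pd.DataFrame(
            {"context": ctx, "kind": kind, "patient_id": ""},
            index=values.columns,
        )
        return ExpressionMatrix(values=values, samples=meta)


@dataclass
class FoldChangeSummary:
    """Per gene x cancer fold-change summaries.

    ``patient_ratios`` maps cancer label -> genes x patients ratio matrix;
    the remaining frames are genes x cancers.  MAD is the raw (unscaled)
    median absolute deviation of the per-patient ratios.
    """

    patient_ratios: dict[str, pd.DataFrame]
    median_ratio: pd.DataFrame
    log2_median_ratio: pd.DataFrame
    mad_ratio: pd.DataFrame
    n_patients: pd.Series

    @property
    def cancers(self) -> list[str]:
        return list(self.median_ratio.columns)

    @property
    def genes(self) -> pd.Index:
        return self.median_ratio.index


@dataclass
class DysregulationCall:
    """Per-gene strongly-upregulated (SUR) calls.

    ``table`` has columns ``n_cancers_above`` and ``is_sur``; a gene is SUR
    iff its median fold change reaches ``ratio_threshold`` in at least
    ``min_cancers`` cancers.
    """

    table: pd.DataFrame
    ratio_threshold: float
    min_cancers: int
    scale: str = "ratio"

    @property
    def sur_genes(self) -> frozenset:
        t = self.table
        return frozenset(t.index[t["is_sur"]])


@dataclass
class VariabilityClass:
    """Low/medium/high expression-variability labels for one cancer.

    High means MAD strictly above the ``q_high`` percentile of that cancer's
    MAD distribution, low strictly below ``q_low``; ties fall to medium.
    """

    cancer: str
    mad: pd.Series
    label: pd.Series
    q_low: float = 25.0
    q_high: float = 75.0


@dataclass
class ComplexStats:
    """Per-gene protein-complex membership statistics.

    ``table`` columns: ``n_complexes`` (count of complexes containing the
    gene) and ``mean_size`` (mean member count over those complexes; NaN
    when the gene sits in no complex).
    """

    table: pd.DataFrame


@dataclass
class SurvivalCohort:
    """(time, event, expression) records for one patient cohort.

    ``data`` is indexed by patient id with columns ``time`` (> 0) and
    ``event`` (1 = event observed, 0 = censored); ``expression`` is a dense
    genes x patients matrix aligned to the same patients.
    """

    data: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["time"].to_numpy(float)
        e = self.data["event"].to_numpy()
        if (t <= 0).any() or not np.isfinite(t).all():
            raise ValidationError("survival times must be positive and finite")
        if not np.isin(e, (0, 1)).all():
            raise ValidationError("event indicators must be 0 or 1")
        if list(self.expression.columns) != list(self.data.index):
            raise ValidationError("expression columns must match cohort patients")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, float)
        if ((s < -1e-12) | (s > 1 + 1e-12)).any():
            raise ValidationError("survival estimates outside [0, 1]")
        if (np.diff(s) > 1e-12).any():
            raise ValidationError("survival estimates must be non-increasing")
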