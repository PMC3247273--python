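"""Shared containers for expression data, metagenes and analysis results.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
symbols in the row index and sample ids in the columns, holding log10
expression ratios relative to a cohort reference.  The helpers here validate
that convention; the richer results of each analysis step get small
dataclasses so that provenance (discovery parameters, thresholds, sign
conventions) travels with the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression",
    "Metagene",
    "QCReport",
    "PCAResult",
    "AgeModel",
    "CorrelationResult",
    "ClassifierEval",
    "ProjectionReport",
    "StateAssignment",
]


def validate_expression(expr: pd.DataFrame, *, require_finite: bool = True) -> pd.DataFrame:
    """Check an expression DataFrame (genes x samples) and return it.

    Raises ``ValueError`` on duplicate/missing gene symbols or sample ids,
    and on non-finite entries unless ``require_finite`` is False (masked
    missing values are represented as NaN and must be handled explicitly
    by the caller).
    """
    if not isinstance(expr, pd.DataFrame):
        raise TypeError("expression must be a pandas DataFrame (genes x samples)")
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene symbols: {dup}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample ids: {dup}")
    if expr.index.isna().any() or expr.columns.isna().any():
        raise ValueError("missing gene symbols or sample ids")
    if require_finite and not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression contains non-finite values; mask missing entries explicitly")
    return expr


@dataclass
class Metagene:
    """A named gene set with optionally two anti-correlated arms.

    The score of a two-arm metagene is the mean log-ratio of the positive
    arm minus the mean of the negative arm; ``coherence`` is the average
    Pearson correlation of the arm-corrected member genes with the
    metagene's mean profile.
    """

    name: str
    positive_arm: tuple[str, ...]
    negative_arm: tuple[str, ...] = ()
    coherence: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positive_arm = tuple(self.positive_arm)
        self.negative_arm = tuple(self.negative_arm)
        overlap = set(self.positive_arm) & set(self.negative_arm)
        if overlap:
            raise ValueError(f"arms overlap: {sorted(overlap)[:5]}")
        if self.coherence is not None and not -1.0 <= self.coherence <= 1.0 + 1e-12:
            raise ValueError(f"coherence out of [-1, 1]: {self.coherence}")

    @property
    def members(self) -> tuple[str, ...]:
        return self.positive_arm + self.negative_arm

    @property
    def size(self) -> int:
        return len(self.positive_arm) + len(self.negative_arm)

    def arm_sign(self, gene: str) -> int:
        if gene in self.positive_arm:
            return 1
        if gene in self.negative_arm:
            return -1
        return 0


@dataclass
class QCReport:
    """Outcome of the PCA sample quality-control step."""

    removed_sample_ids: tuple[str, ...]
    zscores: pd.DataFrame  # samples x components 1..k
    k: int
    z_max: float


@dataclass
class PCAResult:
    """Leading principal components of a gene-centered expression matrix."""

    component_scores: pd.DataFrame  # samples x PC1..PCk
    gene_loadings: pd.DataFrame  # genes x PC1..PCk
    variance_explained_fraction: np.ndarray
    orientation_anchor: str = "unoriented"

    @property
    def pc1(self) -> pd.Series:
        return self.component_scores.iloc[:, 0]


@dataclass
class AgeModel:
    """OLS line of a biomarker score on chronological age in normals."""

    intercept: float  # score units at age 0
    slope: float  # score units per year
    n: int
    residual_sd: float
    fit_sample_ids: tuple[str, ...] = ()


@dataclass
class CorrelationResult:
    """Pearson correlation with Fisher-z significance."""

    rho: float
    n: int
    z: float
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")


@dataclass
class ClassifierEval:
    """AUROC of a score separating two classes."""

    auroc: float
    n_pos: int
    n_neg: int


@dataclass
class ProjectionReport:
    """Bookkeeping for cross-platform projection of a metagene."""

    n_symbols_matched: int
    n_probes_dropped_for_sign: int
    dropped: tuple[str, ...]
    refined: Metagene
    endpoint_result: CorrelationResult | None = None
    endpoint_pass: bool | None = None


@dataclass
class StateAssignment:
    """Per-sample disease-progression states N0-N3 / A1-A2."""

    states: pd.Series  # sample id -> state label
    co_flags: pd.Series  # sample id -> e.g. "A1" when A2 takes precedence
    thresholds: Mapping[str, float]


def as_series(values: Sequence[float] | pd.Series, index: pd.Index | None = None, name: str | None = None) -> pd.Series:
    """Coerce score-like input into a float Series aligned to *index*."""
    s = pd.Series(values, index=index) if not isinstance(values, pd.Series) else values
    return s.astype(float).rename(name)
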