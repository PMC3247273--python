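"""Intensity normalisation and PCA-based sample quality control.

Raw intensities are converted to log10 ratios against the cohort (batch)
reference: ``value(g, s) = log10(I(g, s) / I0(g))`` where ``I0`` is the
geometric mean intensity of gene *g* over the samples of the batch that *s*
belongs to.  On the log scale each gene therefore sums to zero within its
batch, and reapplying the normalisation is a no-op.

Sample QC standardises the scores of the first *k* principal components and
removes, in a single pass, every sample whose absolute z-score on any of
those components exceeds ``z_max``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import QCReport, validate_expression

logger = logging.getLogger(__name__)

__all__ = ["normalize_to_cohort_mean", "remove_outliers_pca", "pca_sample_scores"]


def normalize_to_cohort_mean(
    intensities: pd.DataFrame,
    batches: pd.Series | None = None,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """log10-ratio of each intensity to its gene's batch geometric mean.

    ``batches`` maps sample id to a batch label (default: one batch).
    Masked (NaN) entries are excluded from the gene means; genes missing in
    more than ``max_missing_frac`` of samples are dropped with a warning.
    Non-positive intensities are an error.
    """
    intensities = validate_expression(intensities, require_finite=False)
    vals = intensities.to_numpy(dtype=float)
    bad = ~np.isnan(vals) & (vals <= 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity {vals[g, s]!r} for gene {intensities.index[g]!r}, "
            f"sample {intensities.columns[s]!r}"
        )

    missing_frac = intensities.isna().mean(axis=1)
    drop = missing_frac > max_missing_frac
    if drop.any():
        logger.warning(
            "dropping %d genes missing in more than %.0f%% of samples",
            int(drop.sum()), 100 * max_missing_frac,
        )
        intensities = intensities.loc[~drop]

    if batches is None:
        batches = pd.Series("all", index=intensities.columns)
    batches = batches.reindex(intensities.columns)
    if batches.isna().any():
        missing = intensities.columns[batches.isna()].tolist()[:5]
        raise ValueError(f"samples without batch label: {missing}")

    log_int = np.log10(intensities)
    out = log_int.copy()
    for batch, cols in batches.groupby(batches).groups.items():
        cols = list(cols)
        if not cols:
            raise ValueError(f"empty batch {batch!r}")
        block = log_int[cols]
        out[cols] = block.sub(block.mean(axis=1, skipna=True), axis=0)
    return out


def pca_sample_scores(expr: pd.DataFrame, k: int) -> pd.DataFrame:
    """Scores of samples on the first *k* PCs of the gene-centered matrix."""
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # center genes; no gene-variance scaling
    # SVD of genes x samples: right singular vectors give sample scores
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    scores = (vt[:k].T * s[:k])  # samples x k
    return pd.DataFrame(scores, index=expr.columns, columns=[f"PC{i + 1}" for i in range(k)])


def remove_outliers_pca(
    expr: pd.DataFrame, k: int = 3, z_max: float = 3.0
) -> tuple[pd.DataFrame, QCReport]:
    """Single-pass removal of samples extreme on the first *k* PCs.

    Component scores are standardised to zero mean / unit variance; samples
    with ``|z| > z_max`` on any of components 1..k are removed.  A matrix
    with no variance yields no removals.
    """
    expr = validate_expression(expr)
    n = expr.shape[1]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of samples ({n})")
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} samples, got {n}")
    scores = pca_sample_scores(expr, k)
    sd = scores.std(axis=0, ddof=1)
    z = scores.sub(scores.mean(axis=0), axis=1)
    nonzero = sd > 0
    z.loc[:, nonzero] = z.loc[:, nonzero].div(sd[nonzero], axis=1)
    z.loc[:, ~nonzero] = 0.0
    removed = z.index[(z.abs() > z_max).any(axis=1)]
    report = QCReport(
        removed_sample_ids=tuple(removed),
        zscores=z,
        k=scores.shape[1],
        z_max=z_max,
    )
    if len(removed):
        logger.info("QC removed %d/%d samples (|z| > %g on PC1..PC%d)", len(removed), n, z_max, k)
    return expr.drop(columns=removed), report
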