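"""The BioAge biomarker: first principal component, surrogate genes,
age regression and extrapolated equivalent age.

The first principal component of the gene-centered expression matrix
captures the dominant axis of variation, which in brain cohorts tracks
biological aging.  Its sign is fixed so that the component increases with a
per-sample anchor (chronological age in normal subjects).  Genes with the
strongest absolute correlation to PC1 form the BioAge surrogate metagene,
whose score — unlike the raw projection — can be carried to other
platforms.  A least-squares line of score on age over the normal cohort
supports the "equivalent age" extrapolation: the chronological age at which
the normal trend would reach a given score level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AgeModel, Metagene, PCAResult, validate_expression
from .preprocess import pca_sample_scores

logger = logging.getLogger(__name__)

__all__ = [
    "first_pc",
    "select_surrogate_genes",
    "fit_age_model",
    "extrapolate_equivalent_age",
    "variance_explained_by_score",
    "gene_score_correlations",
]


def first_pc(
    expr: pd.DataFrame,
    orient_by: pd.Series | None = None,
    anchor_mask: pd.Series | None = None,
    n_components: int = 3,
) -> PCAResult:
    """Leading principal components with an anchored sign convention.

    The PC1 sign is flipped if needed so that the Pearson correlation of
    the PC1 scores with ``orient_by`` (restricted to ``anchor_mask``) is
    non-negative; with chronological age as anchor on normal samples this
    makes BioAge increase with age.
    """
    expr = validate_expression(expr)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("no variance in expression matrix")
    k = min(n_components, len(s))
    total = float((s**2).sum())
    var_frac = (s[:k] ** 2) / total
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(vt[:k].T * s[:k], index=expr.columns, columns=cols)
    loadings = pd.DataFrame(u[:, :k], index=expr.index, columns=cols)

    anchor_desc = "unoriented"
    if orient_by is not None:
        anchor = orient_by.reindex(expr.columns).astype(float)
        if anchor_mask is not None:
            mask = anchor_mask.reindex(expr.columns).fillna(False).astype(bool)
        else:
            mask = pd.Series(True, index=expr.columns)
        mask &= anchor.notna()
        if not mask.any():
            raise ValueError("anchor defined on an empty sample mask")
        a = anchor[mask].to_numpy()
        pc1 = scores.loc[mask, "PC1"].to_numpy()
        if np.ptp(a) == 0:
            logger.warning("orientation anchor constant on mask; PC1 sign left unflipped")
            anchor_desc = "anchor constant; unflipped"
        else:
            rho = np.corrcoef(pc1, a)[0, 1]
            if rho < 0:
                scores["PC1"] = -scores["PC1"]
                loadings["PC1"] = -loadings["PC1"]
            anchor_desc = f"PC1 oriented to correlate >= 0 with anchor on {int(mask.sum())} samples"
    return PCAResult(
        component_scores=scores,
        gene_loadings=loadings,
        variance_explained_fraction=var_frac,
        orientation_anchor=anchor_desc,
    )


def gene_score_correlations(expr: pd.DataFrame, scores: pd.Series) -> pd.Series:
    """Pearson correlation of every gene row with a per-sample score."""
    s = scores.reindex(expr.columns).to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("scores are constant")
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ sc) / denom
    return pd.Series(r, index=expr.index)


def select_surrogate_genes(
    expr: pd.DataFrame,
    scores: pd.Series,
    min_abs_corr: float | None = 0.6,
    top_n_per_sign: int | None = None,
    name: str = "BioAge",
) -> Metagene:
    """Build a two-arm surrogate metagene from score correlations.

    Either keep genes with ``|rho| >= min_abs_corr`` (ties at the threshold
    included) or the ``top_n_per_sign`` strongest per sign.
    """
    if (min_abs_corr is None) == (top_n_per_sign is None):
        raise ValueError("specify exactly one of min_abs_corr or top_n_per_sign")
    r = gene_score_correlations(expr, scores).dropna()
    if top_n_per_sign is not None:
        pos = r[r > 0].nlargest(top_n_per_sign).index
        neg = r[r < 0].nsmallest(top_n_per_sign).index
        rule = {"top_n_per_sign": top_n_per_sign}
    else:
        pos = r.index[r >= min_abs_corr]
        neg = r.index[r <= -min_abs_corr]
        rule = {"min_abs_corr": min_abs_corr}
    if len(pos) + len(neg) == 0:
        raise ValueError(
            f"no gene passes |rho| >= {min_abs_corr}; max |rho| = {r.abs().max():.3f} — lower the threshold"
        )
    return Metagene(name=name, positive_arm=tuple(pos), negative_arm=tuple(neg), params={"selection": rule})


def fit_age_model(scores: pd.Series, ages: pd.Series, normal_mask: pd.Series) -> AgeModel:
    """OLS line of biomarker score on chronological age over normal samples."""
    mask = normal_mask.reindex(scores.index).fillna(False).astype(bool)
    s = scores[mask].astype(float)
    a = ages.reindex(scores.index)[mask].astype(float)
    ok = s.notna() & a.notna()
    s, a = s[ok], a[ok]
    if len(s) < 3:
        raise ValueError(f"need >= 3 normal samples with finite ages, got {len(s)}")
    if np.ptp(a.to_numpy()) == 0:
        raise ValueError("all ages equal; age model degenerate")
    fit = sps.linregress(a.to_numpy(), s.to_numpy())
    resid = s.to_numpy() - (fit.intercept + fit.slope * a.to_numpy())
    ddof = 2 if len(s) > 2 else 1
    return AgeModel(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        n=len(s),
        residual_sd=float(np.sqrt((resid**2).sum() / (len(s) - ddof))),
        fit_sample_ids=tuple(s.index),
    )


def extrapolate_equivalent_age(model: AgeModel, target_score: float) -> float:
    """Invert the normal-cohort age line: the age at which the normal trend
    reaches ``target_score``."""
    if model.slope == 0:
        raise ValueError("age not identifiable: age-model slope is zero")
    return float((target_score - model.intercept) / model.slope)


def variance_explained_by_score(expr_subset: pd.DataFrame, scores: pd.Series) -> float:
    """Fraction of a gene subset's variance captured by the score.

    Per-gene R-squared values are aggregated weighted by gene variance:
    ``sum_g r_g^2 var_g / sum_g var_g``, i.e. the variance captured by
    regressing each gene on the score over the subset's total variance.
    """
    if expr_subset.shape[0] == 0:
        raise ValueError("empty gene subset")
    s = scores.reindex(expr_subset.columns).to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("scores are constant")
    x = expr_subset.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    var_g = (xc**2).sum(axis=1)
    ss_s = (sc**2).sum()
    cov = xc @ sc
    keep = var_g > 0
    if not keep.any():
        raise ValueError("all genes constant in subset")
    captured = (cov[keep] ** 2) / ss_s  # = r^2 * var_g on the sum-of-squares scale
    return float(captured.sum() / var_g[keep].sum())
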