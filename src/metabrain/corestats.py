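"""Core biomarker statistics.

The biomarker score of a metagene in a sample is the mean log10 expression
ratio of its positive-arm genes minus the mean of its negative-arm genes
(plain mean when there is no negative arm).  Coherence is the average
Pearson correlation of the arm-corrected member genes with the metagene's
mean profile.  Correlation significance uses the Fisher z-transform
``atanh(rho) * sqrt(n - 3)`` against the standard normal; multiple testing
uses the Benjamini-Hochberg step-up procedure; classifier performance uses
the rank-statistic AUROC (probability that a random positive sample scores
above a random negative one, ties counted one half); gene-set overlaps use
the hypergeometric upper tail with Bonferroni correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datatypes import ClassifierEval, CorrelationResult, Metagene

logger = logging.getLogger(__name__)

__all__ = [
    "biomarker_score",
    "coherence",
    "pearson_fisher",
    "bh_fdr",
    "auroc",
    "overlap_test",
]


def biomarker_score(expr: pd.DataFrame, metagene: Metagene) -> pd.Series:
    """Score every sample: positive-arm mean minus negative-arm mean.

    Genes absent from *expr* are excluded; per-sample NaN entries are
    excluded from the arm means.  Raises if no member gene is present.
    A warning is logged when more than half of an arm is missing.
    """
    pos = [g for g in metagene.positive_arm if g in expr.index]
    neg = [g for g in metagene.negative_arm if g in expr.index]
    if not pos and not neg:
        missing = list(metagene.members)[:10]
        raise ValueError(f"no member genes of '{metagene.name}' present in expression; missing e.g. {missing}")
    for arm_name, arm, present in (("positive", metagene.positive_arm, pos), ("negative", metagene.negative_arm, neg)):
        if arm and len(present) < 0.5 * len(arm):
            logger.warning(
                "metagene %s: %d/%d genes of the %s arm missing from expression",
                metagene.name, len(arm) - len(present), len(arm), arm_name,
            )
    score = pd.Series(0.0, index=expr.columns, name=metagene.name)
    if pos:
        score = score + expr.loc[pos].mean(axis=0, skipna=True)
    if neg:
        score = score - expr.loc[neg].mean(axis=0, skipna=True)
    all_missing = score.isna()
    if all_missing.any():
        logger.warning("metagene %s: %d samples have no non-missing member genes", metagene.name, int(all_missing.sum()))
    return score


def _arm_corrected(expr: pd.DataFrame, metagene: Metagene) -> pd.DataFrame:
    pos = [g for g in metagene.positive_arm if g in expr.index]
    neg = [g for g in metagene.negative_arm if g in expr.index]
    if len(pos) + len(neg) < 2:
        raise ValueError(f"metagene '{metagene.name}' needs >=2 member genes present")
    parts = []
    if pos:
        parts.append(expr.loc[pos])
    if neg:
        parts.append(-expr.loc[neg])
    return pd.concat(parts, axis=0)


def coherence(expr: pd.DataFrame, metagene: Metagene) -> float:
    """Average correlation of arm-corrected member genes with their mean."""
    corrected = _arm_corrected(expr, metagene)
    if corrected.shape[1] < 3:
        raise ValueError("coherence needs >=3 samples")
    mean_profile = corrected.mean(axis=0).to_numpy()
    if np.ptp(mean_profile) == 0:
        raise ValueError("metagene mean profile is constant; coherence undefined")
    x = corrected.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = mean_profile - mean_profile.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ mc) / denom
    return float(np.nanmean(r))


def pearson_fisher(x, y) -> CorrelationResult:
    """Pearson rho with two-sided p from the Fisher z-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rho = float(np.corrcoef(x, y)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    z = float(np.arctanh(np.clip(rho, -1 + 1e-16, 1 - 1e-16)) * np.sqrt(n - 3))
    p = float(2.0 * sps.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return CorrelationResult(rho=rho, n=n, z=z, p=p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auroc(scores, labels) -> ClassifierEval:
    """Rank-statistic AUROC; equals the Mann-Whitney pair-counting value."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if np.ptp(s) == 0:
        value = 0.5  # all tied: every pair counts one half
    else:
        value = float(roc_auc_score(y, s))
    return ClassifierEval(auroc=value, n_pos=n_pos, n_neg=n_neg)


def overlap_test(set_a, set_b, universe_size: int, n_tests: int = 1) -> tuple[float, float]:
    """Hypergeometric upper-tail p for the overlap of two gene sets.

    Returns ``(p, bonferroni_p)`` where the Bonferroni value is
    ``min(1, p * n_tests)``.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    k = len(a & b)
    # P(X >= k) drawing |b| from a universe containing |a| marked genes
    p = float(sps.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    p = min(p, 1.0)
    return p, min(1.0, p * n_tests)
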