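"""Supervised metagene discovery.

The route to disease metagenes is supervised: select samples with matched
moderate BioAge so the dominant aging axis cannot masquerade as disease
signal, find genes differentially expressed between diagnosis groups
(two-group t-test, fold-change and Benjamini-Hochberg FDR filters),
agglomeratively cluster them with Pearson correlation distance
``d = 1 - rho`` (average linkage), and cut the dendrogram into maximal
branches of at least ``min_size`` genes whose coherence — average
correlation of arm-corrected members with the metagene mean — reaches
``min_coherence``.  Anti-correlated arms are reunited post hoc at the
metagene level by :func:`assign_arms` rather than at the linkage level.

The early-aging variant restricts the cohort to normal samples with low
BioAge and clusters the age-upregulated candidate genes there, where an
early factor still varies while the global aging axis is range-restricted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .bioage import gene_score_correlations
from .corestats import bh_fdr, coherence
from .datatypes import Metagene

logger = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "matched_subset",
    "Dendrogram",
    "cluster_genes",
    "assign_arms",
    "cut_to_metagenes",
    "discover_early_metagene",
    "rank_metagenes_by_regulation",
]

_VAR_FLOOR = 1e-12


def differential_expression(
    expr: pd.DataFrame,
    group_labels: pd.Series,
    p_max: float = 0.005,
    fc_min_log10: float = float(np.log10(1.25)),
    fdr_max: float = 0.1,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-group differential expression with p, fold-change and FDR filters.

    ``group_labels`` must take exactly two values over the samples of
    *expr*.  The default pooled-variance t-test is the two-group ANOVA;
    ``equal_var=False`` selects the Welch variant.  Fold change is the
    difference of group-mean log10 ratios.  Returns a per-gene DataFrame
    with means, fold change, t, p, BH q and a ``passed`` flag requiring
    ``p < p_max``, ``|fc| > fc_min_log10`` and ``q < fdr_max``.
    """
    labels = group_labels.reindex(expr.columns).dropna()
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    cols_a = labels.index[labels == groups[0]]
    cols_b = labels.index[labels == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"each group needs >= 2 samples (got {len(cols_a)}, {len(cols_b)})")
    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (var_a < _VAR_FLOOR) & (var_b < _VAR_FLOOR)
    if degenerate.any():
        logger.warning("%d genes with (near) zero within-group variance; variance floored", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(
            a, b, axis=1, equal_var=equal_var,
        )
    # zero-variance genes: p = 1 when means equal, else variance-floored t-test
    if degenerate.any():
        na, nb = a.shape[1], b.shape[1]
        if equal_var:
            se = np.sqrt(_VAR_FLOOR * (1 / na + 1 / nb))
            df = na + nb - 2
        else:
            se = np.sqrt(_VAR_FLOOR / na + _VAR_FLOOR / nb)
            df = na + nb - 2
        t_floor = (mean_a - mean_b) / se
        p_floor = 2 * sps.t.sf(np.abs(t_floor), df)
        equal_means = degenerate & (np.abs(mean_a - mean_b) < 1e-300)
        t = np.where(degenerate, t_floor, t)
        p = np.where(degenerate, p_floor, p)
        t = np.where(equal_means, 0.0, t)
        p = np.where(equal_means, 1.0, p)
    fc = mean_a - mean_b
    q = bh_fdr(p)
    passed = (p < p_max) & (np.abs(fc) > fc_min_log10) & (q < fdr_max)
    return pd.DataFrame(
        {
            f"mean_{groups[0]}": mean_a,
            f"mean_{groups[1]}": mean_b,
            "log10_fold_change": fc,
            "t": t,
            "p": p,
            "q": q,
            "passed": passed,
        },
        index=expr.index,
    )


def matched_subset(scores: pd.Series, window: tuple[float, float] = (-0.1, 0.3)) -> pd.Index:
    """Sample ids whose score lies in the closed interval ``window``."""
    s = scores.astype(float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    lo, hi = window
    selected = s.index[(s >= lo) & (s <= hi)]
    if len(selected) == 0:
        raise ValueError(f"no samples with score in [{lo}, {hi}]; widen the window")
    return selected


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes with correlation-distance heights."""

    linkage: np.ndarray  # scipy linkage matrix
    genes: tuple[str, ...]
    distance: str = "one_minus_corr"

    @property
    def n_leaves(self) -> int:
        return len(self.genes)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.genes[node.id]
            left, right = rec(node.left), rec(node.right)
            return f"({left}:{node.dist - node.left.dist:.6g},{right}:{node.dist - node.right.dist:.6g})"

        return rec(tree) + ";"


def cluster_genes(
    expr: pd.DataFrame,
    gene_subset=None,
    distance: str = "one_minus_corr",
) -> Dendrogram:
    """Agglomerative average-linkage clustering on correlation distance.

    ``distance`` is ``one_minus_corr`` (d = 1 - rho; anti-correlated arms
    are reunited later by :func:`assign_arms`) or ``one_minus_abs_corr``.
    Constant gene rows are dropped with a warning.
    """
    sub = expr.loc[list(gene_subset)] if gene_subset is not None else expr
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster genes")
    x = sub.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    if constant.any():
        logger.warning("dropping %d constant gene rows before clustering", int(constant.sum()))
        sub = sub.loc[~constant]
        x = sub.to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 non-constant genes to cluster")
    corr = np.corrcoef(x)
    if distance == "one_minus_corr":
        d = 1.0 - corr
    elif distance == "one_minus_abs_corr":
        d = 1.0 - np.abs(corr)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    condensed = d[np.triu_indices_from(d, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=linkage, genes=tuple(sub.index), distance=distance)


def assign_arms(expr: pd.DataFrame, gene_set) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split a gene set into anti-correlated positive and negative arms.

    Two-pass: sign each gene by its correlation with the raw mean profile,
    then re-sign against the arm-corrected mean.  Orientation is fixed so
    the positive arm is the larger (ties: the arm containing the
    lexicographically smallest symbol is positive).
    """
    genes = list(gene_set)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes to assign arms")
    x = expr.loc[genes].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)

    def signs_vs(profile: np.ndarray) -> np.ndarray:
        pc = profile - profile.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = xc @ pc
        return np.where(r >= 0, 1, -1)

    sign1 = signs_vs(x.mean(axis=0))
    sign2 = signs_vs((xc * sign1[:, None]).mean(axis=0))
    pos = [g for g, s in zip(genes, sign2) if s > 0]
    neg = [g for g, s in zip(genes, sign2) if s < 0]
    flip = len(neg) > len(pos) or (len(neg) == len(pos) and neg and pos and min(neg) < min(pos))
    if flip:
        pos, neg = neg, pos
    return tuple(pos), tuple(neg)


def _branch_members(linkage: np.ndarray, genes: tuple[str, ...]) -> dict[int, list[int]]:
    """Leaf indices under every node id of a scipy linkage."""
    n = len(genes)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, (a, b, _, _) in enumerate(linkage):
        members[n + i] = members[int(a)] + members[int(b)]
    return members


def cut_to_metagenes(
    dendrogram: Dendrogram,
    expr: pd.DataFrame,
    min_size: int = 200,
    min_coherence: float = 0.75,
    allow_arms: bool = True,
    name_prefix: str = "metagene",
    min_arm_size: int | None = None,
    split_improvement: float = 0.04,
) -> list[Metagene]:
    """Cut the dendrogram into maximal coherent branches and reunite
    anti-correlated branch pairs into two-arm metagenes.

    Under the correlation distance ``d = 1 - rho`` the two arms of a
    two-arm metagene sit on opposite ends of the tree, so the cut proceeds
    in two steps.  First, the most inclusive branches whose coherence
    reaches ``min_coherence`` and whose size is at least ``min_arm_size``
    (default ``min_size // 4``) are collected top-down; descendants of a
    qualifying branch are suppressed.  A branch that only just clears the
    bar because it lumps two distinct tight clusters together is split: if
    a child branch improves on the parent's coherence by more than
    ``split_improvement``, descent continues instead of accepting the
    parent (a homogeneous cluster's children improve only marginally).  Second (when ``allow_arms``),
    branch pairs whose mean profiles correlate at or below
    ``-min_coherence`` are merged into two-arm metagenes, most
    anti-correlated pairs first, provided the merged metagene still reaches
    ``min_coherence`` after arm correction.  Branches or merged pairs of
    fewer than ``min_size`` genes are discarded.  Returns metagenes sorted
    by size (largest first); an empty list when none qualify.
    """
    if min_arm_size is None:
        min_arm_size = max(2, min_size // 4)
    if dendrogram.n_leaves < min(min_size, min_arm_size):
        return []
    members = _branch_members(dendrogram.linkage, dendrogram.genes)
    n = dendrogram.n_leaves
    root = n + len(dendrogram.linkage) - 1

    branches: list[list[str]] = []

    def branch_coherence(genes: list[str]) -> float | None:
        mg = Metagene(name="candidate", positive_arm=tuple(genes))
        try:
            return coherence(expr, mg)
        except ValueError:
            return None

    def visit(node: int) -> None:
        genes = [dendrogram.genes[i] for i in members[node]]
        children = []
        if node >= n:
            a, b = dendrogram.linkage[node - n, :2]
            children = [int(a), int(b)]
        if len(genes) >= min_arm_size:
            coh = branch_coherence(genes)
            if coh is not None and coh >= min_coherence:
                lumped = False
                for child in children:
                    child_genes = [dendrogram.genes[i] for i in members[child]]
                    if len(child_genes) < min_arm_size:
                        continue
                    child_coh = branch_coherence(child_genes)
                    if child_coh is not None and child_coh >= coh + split_improvement:
                        lumped = True
                        break
                if not lumped:
                    branches.append(genes)
                    return  # maximal homogeneous branch: do not descend
        for child in children:
            visit(child)

    visit(root)

    def trim_and_qualify(pos: tuple[str, ...], neg: tuple[str, ...]) -> Metagene | None:
        """Drop hangers-on (arm-corrected correlation with the metagene mean
        below half the coherence bar), then re-check size and coherence."""
        floor = 0.5 * min_coherence
        corrected = pd.concat(
            ([expr.loc[list(pos)]] if pos else []) + ([-expr.loc[list(neg)]] if neg else [])
        )
        mean = corrected.mean(axis=0).to_numpy()
        x = corrected.to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        mc = mean - mean.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ mc) / np.sqrt((xc**2).sum(axis=1) * (mc**2).sum())
        keep = set(np.asarray(corrected.index)[r >= floor])
        pos = tuple(g for g in pos if g in keep)
        neg = tuple(g for g in neg if g in keep)
        if len(pos) + len(neg) < min_size:
            return None
        mg = Metagene(name="candidate", positive_arm=pos, negative_arm=neg)
        coh = coherence(expr, mg)
        if coh < min_coherence:
            return None
        mg.coherence = coh
        return mg

    found: list[Metagene] = []
    if allow_arms and len(branches) > 1:
        profiles = [expr.loc[genes].mean(axis=0).to_numpy() for genes in branches]
        pairs = []
        for i in range(len(branches)):
            for j in range(i + 1, len(branches)):
                if np.ptp(profiles[i]) == 0 or np.ptp(profiles[j]) == 0:
                    continue
                rho = float(np.corrcoef(profiles[i], profiles[j])[0, 1])
                if rho <= -min_coherence:
                    pairs.append((rho, i, j))
        used: set[int] = set()
        for rho, i, j in sorted(pairs):
            if i in used or j in used:
                continue
            union = branches[i] + branches[j]
            if len(union) < min_size:
                continue
            pos, neg = assign_arms(expr, union)
            mg = trim_and_qualify(pos, neg)
            if mg is not None:
                found.append(mg)
                used.update((i, j))
        branches = [b for k, b in enumerate(branches) if k not in used]

    for genes in branches:
        if len(genes) < min_size:
            continue
        if allow_arms:
            pos, neg = assign_arms(expr, genes)
        else:
            pos, neg = tuple(genes), ()
        mg = trim_and_qualify(pos, neg)
        if mg is not None:
            found.append(mg)

    found.sort(key=lambda m: (-m.size, -(m.coherence or 0.0)))
    out = []
    for i, mg in enumerate(found, start=1):
        out.append(
            Metagene(
                name=f"{name_prefix}_{i}",
                positive_arm=mg.positive_arm,
                negative_arm=mg.negative_arm,
                coherence=mg.coherence,
                params={"min_size": min_size, "min_coherence": min_coherence, "allow_arms": allow_arms,
                        "distance": dendrogram.distance},
            )
        )
    if not out:
        logger.info("no branch with size >= %d and coherence >= %g", min_size, min_coherence)
    return out


def rank_metagenes_by_regulation(
    metagenes: list[Metagene], expr: pd.DataFrame, group_labels: pd.Series
) -> list[Metagene]:
    """Order metagenes by between-group variance of their scores (most
    regulated first)."""
    from .corestats import biomarker_score

    labels = group_labels.reindex(expr.columns)

    def between_var(mg: Metagene) -> float:
        score = biomarker_score(expr, mg)
        overall = score.mean()
        parts = [
            len(grp) * (score[grp.index].mean() - overall) ** 2
            for _, grp in labels.groupby(labels)
        ]
        return float(sum(parts) / len(score))

    return sorted(metagenes, key=between_var, reverse=True)


def discover_early_metagene(
    expr: pd.DataFrame,
    bioage_scores: pd.Series,
    cohort_mask: pd.Series,
    bioage_max: float = 0.0,
    min_size: int = 200,
    min_coherence: float = 0.75,
    candidate_min_corr: float = 0.2,
    exclude_genes=None,
    name: str = "Lipa",
) -> Metagene | None:
    """Find the early-aging (Lipa-like) metagene in low-BioAge normals.

    Candidate genes are those upregulated with BioAge (correlation with the
    BioAge score over the masked cohort >= ``candidate_min_corr``).  They
    are clustered over the masked samples whose BioAge score is at most
    ``bioage_max``, where an early factor still has most of its dynamic
    range while the global aging axis is range-restricted.  Among
    qualifying metagenes the one with "exceptionally high" mutual
    correlation — the highest coherence — is returned; None when nothing
    qualifies.
    """
    mask = cohort_mask.reindex(expr.columns).fillna(False).astype(bool)
    if not mask.any():
        raise ValueError("cohort mask selects no samples")
    scores = bioage_scores.reindex(expr.columns)
    masked_cols = expr.columns[mask]
    low = masked_cols[scores[masked_cols] <= bioage_max]
    if len(low) < 10:
        raise ValueError(
            f"only {len(low)} masked samples with BioAge <= {bioage_max}; need >= 10"
        )
    r = gene_score_correlations(expr[masked_cols], scores[masked_cols])
    candidates = r.index[r >= candidate_min_corr]
    if exclude_genes is not None:
        # the primary aging surrogate is already known; the early metagene
        # is the additional structure among the remaining age-coupled genes
        candidates = candidates.difference(set(exclude_genes), sort=False)
    if len(candidates) < min_size:
        logger.info("only %d age-upregulated candidate genes (< min_size)", len(candidates))
        return None
    dend = cluster_genes(expr[low], gene_subset=candidates)
    metagenes = cut_to_metagenes(
        dend, expr[low], min_size=min_size, min_coherence=min_coherence, name_prefix=name
    )
    if not metagenes:
        return None
    best = max(metagenes, key=lambda m: m.coherence or -1.0)
    return Metagene(
        name=name,
        positive_arm=best.positive_arm,
        negative_arm=best.negative_arm,
        coherence=best.coherence,
        params={**best.params, "bioage_max": bioage_max, "candidate_min_corr": candidate_min_corr},
    )
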