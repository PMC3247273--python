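"""Cross-platform projection of a metagene onto an independent dataset.

Symbols are matched case-insensitively against the target matrix; a
provisional score is computed from all matched probes with their original
arm signs; probes whose arm-adjusted correlation with that provisional
score is negative ("opposite regulation according to the sign") are
dropped in a single refinement pass, and the score is recomputed from the
refined set.  The projected score is then validated against a per-sample
endpoint (age, disease severity) by Fisher-z correlation with an expected
direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corestats import biomarker_score, pearson_fisher
from .datatypes import CorrelationResult, Metagene, ProjectionReport

logger = logging.getLogger(__name__)

__all__ = ["map_and_refine", "validate_against_endpoint"]


def _match_symbols(symbols, target_index) -> dict[str, list[str]]:
    """Map metagene symbols (case-insensitive) to target row labels."""
    by_lower: dict[str, list[str]] = {}
    for label in target_index:
        by_lower.setdefault(str(label).lower(), []).append(label)
    matches = {}
    for sym in symbols:
        hit = by_lower.get(str(sym).lower())
        if hit:
            matches[sym] = hit
    return matches


def map_and_refine(
    metagene: Metagene,
    target_expr: pd.DataFrame,
    iterate_to_fixed_point: bool = False,
    max_iter: int = 10,
) -> tuple[Metagene, ProjectionReport]:
    """Project a metagene onto a target platform with sign-based refinement.

    Returns the refined metagene (arms expressed in the target's probe
    labels) and a report of matches and drops.  By default a single
    refinement pass is applied; ``iterate_to_fixed_point`` repeats until no
    probe is dropped.
    """
    pos_match = _match_symbols(metagene.positive_arm, target_expr.index)
    neg_match = _match_symbols(metagene.negative_arm, target_expr.index)
    pos = [probe for hits in pos_match.values() for probe in hits]
    neg = [probe for hits in neg_match.values() for probe in hits]
    n_matched = len(pos) + len(neg)
    if n_matched < 2:
        raise ValueError(f"only {n_matched} probes of '{metagene.name}' matched on the target platform")

    def refine_once(p: list[str], n: list[str]) -> tuple[list[str], list[str], list[str]]:
        provisional = biomarker_score(
            target_expr, Metagene(name="provisional", positive_arm=tuple(p), negative_arm=tuple(n))
        ).to_numpy()
        if np.ptp(provisional) == 0:
            raise ValueError("provisional projected score is constant; cannot refine")
        x = target_expr.loc[p + n].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        pc = provisional - provisional.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ pc) / np.sqrt((xc**2).sum(axis=1) * (pc**2).sum())
        arm = np.array([1] * len(p) + [-1] * len(n))
        adjusted = r * arm
        keep = adjusted >= 0
        probes = p + n
        dropped = [probes[i] for i in range(len(probes)) if not keep[i]]
        new_p = [g for g, k in zip(p, keep[: len(p)]) if k]
        new_n = [g for g, k in zip(n, keep[len(p):]) if k]
        return new_p, new_n, dropped

    dropped_all: list[str] = []
    new_pos, new_neg, dropped = refine_once(pos, neg)
    dropped_all.extend(dropped)
    if iterate_to_fixed_point:
        for _ in range(max_iter - 1):
            if not dropped or not (new_pos or new_neg):
                break
            new_pos, new_neg, dropped = refine_once(new_pos, new_neg)
            dropped_all.extend(dropped)
    if not new_pos and not new_neg:
        raise ValueError("all matched probes dropped during sign refinement")
    refined = Metagene(
        name=metagene.name,
        positive_arm=tuple(new_pos),
        negative_arm=tuple(new_neg),
        params={"projected_from": metagene.name, "n_matched": n_matched,
                "single_pass": not iterate_to_fixed_point},
    )
    report = ProjectionReport(
        n_symbols_matched=n_matched,
        n_probes_dropped_for_sign=len(dropped_all),
        dropped=tuple(dropped_all),
        refined=refined,
    )
    logger.info(
        "projection of %s: %d probes matched, %d dropped for opposite sign",
        metagene.name, n_matched, len(dropped_all),
    )
    return refined, report


def validate_against_endpoint(
    scores: pd.Series,
    endpoint: pd.Series,
    direction: int,
    alpha: float = 0.05,
) -> tuple[CorrelationResult, bool]:
    """Correlate a projected score with an endpoint and check the direction.

    ``direction`` is +1 or -1, the expected sign of the correlation.  The
    pass flag requires the observed sign to match and ``p < alpha``.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    s = scores.astype(float)
    e = endpoint.reindex(s.index).astype(float)
    if len(e) != len(s):
        raise ValueError("score/endpoint length mismatch")
    result = pearson_fisher(s.to_numpy(), e.to_numpy())
    passed = bool(np.sign(result.rho) == direction and result.p < alpha)
    return result, passed
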