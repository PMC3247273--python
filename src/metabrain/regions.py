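"""Cross-region systemic-vs-localized analysis and progression states.

Systemic biomarkers (BioAge, Lipa, Inflame, NdStress) measure processes
that span brain regions, so their per-subject scores correlate strongly
between regions; the AD-specific Alz biomarker is confined to affected
regions and does not.  The biomarker activation ordering is tested as
quadrant emptiness (no sample with high NdStress but low Inflame) with a
Monte-Carlo permutation null.  The progression state model assigns each
sample to one of six cross-sectional states:

* N0 — all biomarkers low;
* N1 — early lipid-metabolism activation (Lipa high);
* N2 — inflammation joins (Lipa and Inflame high);
* N3 — continued aging (as N2 with high BioAge) without disease markers;
* A1 — neurodegenerative stress active (NdStress high);
* A2 — the AD-specific program active (Alz high; takes precedence over A1
  with an A1 co-flag when both are high).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corestats import pearson_fisher
from .datatypes import CorrelationResult, StateAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "make_region_score_table",
    "cross_region_correlation",
    "quadrant_ordering_test",
    "default_state_thresholds",
    "assign_states",
]


def make_region_score_table(scores_by_region: dict[str, pd.DataFrame], annotation_by_region: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format table (subject, region, biomarker, score).

    ``scores_by_region`` maps region label to a samples x biomarkers score
    frame; ``annotation_by_region`` supplies the sample -> subject mapping.
    """
    rows = []
    for region, scores in scores_by_region.items():
        ann = annotation_by_region[region]
        subj = ann["subject"].reindex(scores.index)
        for biomarker in scores.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subj.to_numpy(),
                        "region": region,
                        "biomarker": biomarker,
                        "score": scores[biomarker].to_numpy(),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    if table.duplicated(["subject", "region", "biomarker"]).any():
        raise ValueError("duplicate (subject, region, biomarker) entries")
    return table


def cross_region_correlation(
    table: pd.DataFrame, biomarker: str, region_a: str, region_b: str
) -> CorrelationResult:
    """Fisher-z correlation of a biomarker's per-subject scores between two
    regions; subjects present in only one region are excluded."""
    sub = table[table["biomarker"] == biomarker]
    a = sub[sub["region"] == region_a].set_index("subject")["score"]
    b = sub[sub["region"] == region_b].set_index("subject")["score"]
    common = a.index.intersection(b.index)
    if len(common) < 4:
        raise ValueError(f"only {len(common)} subjects with {biomarker} in both regions; need >= 4")
    return pearson_fisher(a[common].to_numpy(), b[common].to_numpy())


def quadrant_ordering_test(
    score_a,
    score_b,
    hi_a: float,
    lo_b: float,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Count samples with ``score_a > hi_a`` and ``score_b < lo_b``.

    An empty quadrant supports the ordering claim that the process behind
    *b* activates before the process behind *a*.  The permutation p-value
    is the Monte-Carlo probability of observing a count as small or smaller
    under random re-pairing of the two score vectors.
    Returns ``(count, fraction, permutation_p)``.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    high_a = a > hi_a
    low_b = b < lo_b
    count = int((high_a & low_b).sum())
    n = a.size
    rng = np.random.default_rng(seed)
    leq = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if int((high_a & low_b[perm]).sum()) <= count:
            leq += 1
    p = (leq + 1) / (n_permutations + 1)
    return count, count / n if n else 0.0, p


def default_state_thresholds(
    scores: pd.DataFrame, diagnosis: pd.Series | None = None
) -> dict[str, float]:
    """Cohort-quantile thresholds: "high" = top tercile boundary per
    biomarker; the BioAge boundary for N3 is the AD-cohort median when a
    diagnosis is supplied, the top tercile otherwise."""
    thresholds = {c: float(scores[c].quantile(2 / 3)) for c in scores.columns}
    if "bioage" in scores.columns and diagnosis is not None:
        ad = diagnosis.reindex(scores.index) == "AD"
        if ad.any():
            thresholds["bioage"] = float(scores.loc[ad, "bioage"].median())
    return thresholds


_REQUIRED = ("lipa", "inflame", "ndstress", "alz")


def assign_states(scores: pd.DataFrame, thresholds: dict[str, float]) -> StateAssignment:
    """Deterministic progression-state assignment from biomarker scores.

    ``scores`` needs columns lipa, inflame, ndstress, alz and, for the
    N2/N3 distinction, bioage.  Precedence: A2 (alz high, with an A1
    co-flag when ndstress is also high) > A1 (ndstress high) > N3/N2
    (inflame high, split on bioage) > N1 (lipa high) > N0.
    """
    for col in _REQUIRED:
        if col not in scores.columns:
            raise ValueError(f"missing biomarker column {col!r}")
        bad = scores[col].isna()
        if bad.any():
            raise ValueError(f"missing {col} score for sample {scores.index[bad][0]!r}")
    has_bioage = "bioage" in scores.columns
    states, co_flags = [], []
    for sample, row in scores.iterrows():
        hi = {c: row[c] > thresholds[c] for c in _REQUIRED}
        if has_bioage:
            hi["bioage"] = row["bioage"] > thresholds.get("bioage", np.inf)
        if hi["alz"]:
            states.append("A2")
            co_flags.append("A1" if hi["ndstress"] else "")
        elif hi["ndstress"]:
            states.append("A1")
            co_flags.append("")
        elif hi["inflame"]:
            states.append("N3" if has_bioage and hi["bioage"] else "N2")
            co_flags.append("")
        elif hi["lipa"]:
            states.append("N1")
            co_flags.append("")
        else:
            states.append("N0")
            co_flags.append("")
    return StateAssignment(
        states=pd.Series(states, index=scores.index, name="state"),
        co_flags=pd.Series(co_flags, index=scores.index, name="co_flag"),
        thresholds=dict(thresholds),
    )
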