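"""Synthetic multi-region brain expression cohorts with planted latent structure.

The generator emulates the latent organisation that the analysis pipeline is
designed to recover from postmortem brain profiles:

* **bioage** — a biological-aging factor that increases linearly with
  chronological age in non-demented subjects (0.01 score units per year,
  anchored at 60 y) but is drawn from a high-mean distribution independent
  of age in AD, so that demented brains look prematurely old.
* **lipa** — an early lipid-metabolism factor that activates first, a
  steep soft threshold low on the progression axis, so it is high in every
  diseased subject and in most aged normals.
* **inflame** — an inflammation factor activating after lipa, strongly
  boosted in disease and present in a random subset of non-demented brains.
* **ndstress** — a neurodegenerative-stress factor, exactly zero in all
  non-demented subjects, active in AD and HD once inflammation is on, and
  positively coupled to biological age.
* **alz** — an AD-specific factor, exactly zero in normals, in HD, and in
  every brain region except the single "affected" one.

Activation is ordered by hierarchical gating: inflame is zeroed unless
lipa is past its half-activation point, and ndstress is zeroed unless
inflame is.  The ordering lipa -> inflame -> ndstress therefore holds
*exactly* for every seed — no sample can have high NdStress but low
Inflame — while each factor's activation level runs on its own severity
draw, keeping the factors far enough apart in correlation space for the
discovery pipeline to resolve them.  Per-factor heterogeneity multipliers
and switch-like (jump + saturating) pathology responses model subject
heterogeneity; the lipa multiplier is >= 1 so the gate condition is never
undone by noise.

Each factor drives ``genes_per_factor`` genes with configurable loading
magnitude; a configurable fraction of each factor's genes carries a negated
loading (the metagene's negative arm).  Remaining genes are pure noise.
Expression is gene-wise centered to the cohort mean, emulating log10-ratio
normalisation against the cohort reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FACTORS = ("bioage", "lipa", "inflame", "ndstress", "alz")

__all__ = [
    "FACTORS",
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_multiregion",
    "make_projection_target",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions used throughout the test-suite:
    200 normal, 100 AD and 50 HD subjects and 3000 genes (600 loading on
    the aging factor, 300 on each of lipa/inflame/ndstress/alz, the rest
    pure noise), on the log10-ratio scale.
    """

    n_normal: int = 200
    n_ad: int = 100
    n_hd: int = 50
    n_genes: int = 3000
    genes_per_factor: dict | int = field(
        default_factory=lambda: {"bioage": 600, "lipa": 300, "inflame": 300, "ndstress": 300, "alz": 300}
    )
    age_range_normal: tuple[float, float] = (60.0, 95.0)
    age_range_ad: tuple[float, float] = (65.0, 95.0)
    factor_effect_sizes: dict = field(
        default_factory=lambda: {"bioage": 1.3, "lipa": 0.45, "inflame": 0.18, "ndstress": 0.8, "alz": 0.8}
    )
    noise_sd: float = 0.06
    frac_negative_arm: dict | float = field(
        default_factory=lambda: {"bioage": 0.5, "lipa": 0.0, "inflame": 0.0, "ndstress": 0.4, "alz": 0.0}
    )
    regions: tuple[str, ...] = ("PFC", "VC")
    affected_region: str = "PFC"
    local_factors: tuple[str, ...] = ("alz",)
    factors: tuple[str, ...] = FACTORS
    seed: int = 0
    # latent-scale parameters (log10 score units unless noted)
    bioage_slope_per_year: float = 0.01
    bioage_anchor_age: float = 60.0
    bioage_scatter_sd: float = 0.15  # individual deviation from the age line
    ad_bioage_mean: float = 0.40
    ad_bioage_sd: float = 0.20
    hd_bioage_mean: float = 0.35
    hd_bioage_sd: float = 0.20
    # diseased brains never present with low biological age: draws below the
    # floor are reflected upward, which also guarantees the early (Lipa)
    # factor is active in every diseased subject
    disease_bioage_floor: float = 0.15
    progression_jitter_sd: float = 0.10
    progression_jitter_clip: float = 0.15
    disease_inflammation_boost: float = 0.45
    disease_progression_boost: float = 0.32  # boost for ndstress/alz arguments
    # weight of the aging/progression axis in the disease-factor argument;
    # below 1 it loosens the coupling between disease activation and
    # biological age without touching the activation ordering guarantees
    progression_weight: float = 0.25
    # per-subject severity jitters feeding the disease factors: they
    # decouple disease activation from the aging axis; each factor draws
    # its own, so the disease factors stay mutually resolvable
    severity_jitter_sd: float = 0.12
    disease_severity_sd: float = 0.25
    # a fraction of non-demented brains carries age-independent
    # inflammation (infection, injury); the boost is gated on progression
    # past the lipa threshold so the activation ordering stays exact
    normal_inflammation_rate: float = 0.10
    normal_inflammation_boost: float = 0.35
    normal_inflammation_min_p: float = 0.0
    lipa_threshold: float = -0.05
    lipa_width: float = 0.10
    inflame_threshold: float = 0.30
    inflame_width: float = 0.06
    ndstress_threshold: float = 0.25
    alz_threshold: float = 0.28
    # one-sided (upward) per-sample threshold jitters model variability in
    # the onset point of each program
    inflame_threshold_jitter_sd: float = 0.03
    ndstress_threshold_jitter_sd: float = 0.04
    alz_threshold_jitter_sd: float = 0.06
    # lipa amplitude multiplier is exp(|N(0, sd)|) >= 1, so heterogeneity
    # never pulls an active sample below the activation point used by the
    # inflame gate
    lipa_heterogeneity_sd: float = 0.40
    # inflame amplitude multiplier is 1 + min(|N(0, sd)|, cap)
    inflame_heterogeneity_sd: float = 0.8
    inflame_heterogeneity_cap: float = 1.4
    heterogeneity_sd: float = 0.7  # ndstress severity multiplier, clipped lognormal
    alz_heterogeneity_sd: float = 0.7
    # pathology onset is switch-like: at activation the latent jumps, then
    # grows with progression excess and saturates, concentrating the
    # disease contrast at moderate progression
    ndstress_jump: float = 0.30
    ndstress_saturation: float = 0.25
    alz_jump: float = 0.25
    alz_saturation: float = 0.25

    def frac_negative(self, factor: str) -> float:
        if isinstance(self.frac_negative_arm, dict):
            return float(self.frac_negative_arm.get(factor, 0.0))
        return float(self.frac_negative_arm)

    def n_factor_genes(self, factor: str) -> int:
        if isinstance(self.genes_per_factor, dict):
            return int(self.genes_per_factor.get(factor, 0))
        return int(self.genes_per_factor)

    def validate(self) -> None:
        for name in ("n_normal", "n_ad", "n_hd", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        total_factor_genes = sum(self.n_factor_genes(f) for f in self.factors)
        if any(self.n_factor_genes(f) < 0 for f in self.factors):
            raise ValueError("genes_per_factor must be >= 0 for every factor")
        if total_factor_genes > self.n_genes:
            raise ValueError(
                f"genes_per_factor summed over factors ({total_factor_genes}) exceeds n_genes ({self.n_genes})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for f in self.factors:
            fr = self.frac_negative(f)
            if not 0.0 <= fr <= 1.0:
                raise ValueError(f"frac_negative_arm[{f}] must be in [0, 1], got {fr}")
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("regions must be unique labels")

    def validate_multiregion(self) -> None:
        self.validate()
        if len(self.regions) < 2:
            raise ValueError("multiregion generation needs >= 2 regions")
        if list(self.regions).count(self.affected_region) != 1:
            raise ValueError(f"exactly one affected region required; got {self.affected_region!r} in {self.regions}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("age_range_normal", "age_range_ad", "regions", "local_factors", "factors"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery testing."""

    latent_factors: pd.DataFrame  # samples x factors
    loadings: pd.DataFrame  # genes x factors, signed
    arm_sign: pd.DataFrame  # genes x factors in {-1, 0, +1}
    annotation: pd.DataFrame  # sample id -> diagnosis, age, region, subject
    activation_thresholds: dict

    def factor_genes(self, factor: str) -> list[str]:
        return self.arm_sign.index[self.arm_sign[factor] != 0].tolist()


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, gene-wise centered log-ratios
    annotation: pd.DataFrame  # sample id -> diagnosis, age, region, subject
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
        self.annotation.to_csv(out / "annotation.csv", index_label="sample_id")
        self.truth.latent_factors.to_csv(out / "truth_latents.csv", index_label="sample_id")
        self.truth.arm_sign.to_csv(out / "truth_arm_sign.csv", index_label="gene")


def _subject_latents(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject diagnosis, age and systemic latent factor values."""
    n = config.n_normal + config.n_ad + config.n_hd
    diagnosis = np.array(["normal"] * config.n_normal + ["AD"] * config.n_ad + ["HD"] * config.n_hd)
    lo_n, hi_n = config.age_range_normal
    lo_d, hi_d = config.age_range_ad
    age = np.empty(n)
    age[: config.n_normal] = rng.uniform(lo_n, hi_n, config.n_normal)
    age[config.n_normal:] = rng.uniform(lo_d, hi_d, config.n_ad + config.n_hd)

    is_ad = diagnosis == "AD"
    is_hd = diagnosis == "HD"
    is_dis = is_ad | is_hd

    bioage = config.bioage_slope_per_year * (age - config.bioage_anchor_age)
    bioage = bioage + rng.normal(0.0, config.bioage_scatter_sd, n)
    bioage[is_ad] = rng.normal(config.ad_bioage_mean, config.ad_bioage_sd, int(is_ad.sum()))
    bioage[is_hd] = rng.normal(config.hd_bioage_mean, config.hd_bioage_sd, int(is_hd.sum()))
    floor = config.disease_bioage_floor
    bioage[is_dis] = np.where(bioage[is_dis] < floor, 2 * floor - bioage[is_dis], bioage[is_dis])

    # progression axis p drives lipa; the disease factors run on their own
    # severity draws and are gated hierarchically (inflame requires active
    # lipa, ndstress requires active inflame), which makes the activation
    # ordering exact by construction for every seed
    jc = config.progression_jitter_clip
    p = bioage + np.clip(rng.normal(0.0, config.progression_jitter_sd, n), -jc, jc)

    lipa = _sigmoid((p - config.lipa_threshold) / config.lipa_width)
    lipa = lipa * np.exp(np.abs(rng.normal(0.0, config.lipa_heterogeneity_sd, n)))  # >=1 multiplier

    def severity(rng: np.random.Generator) -> np.ndarray:
        draw_n = rng.normal(0.0, config.severity_jitter_sd, n)
        draw_d = rng.normal(0.0, config.disease_severity_sd, n)
        return np.where(is_dis, draw_d, draw_n)

    boost_i = config.disease_inflammation_boost * is_dis.astype(float)
    boost = config.disease_progression_boost * is_dis.astype(float)
    inflamed_normal = (
        (~is_dis)
        & (rng.random(n) < config.normal_inflammation_rate)
        & (p > config.normal_inflammation_min_p)
    )
    wp = config.progression_weight
    arg_i = wp * p + severity(rng) + boost_i + config.normal_inflammation_boost * inflamed_normal.astype(float)
    t_inflame = config.inflame_threshold + np.abs(rng.normal(0.0, config.inflame_threshold_jitter_sd, n))
    inflame = _sigmoid((arg_i - t_inflame) / config.inflame_width)
    inflame = inflame * (1.0 + np.minimum(
        np.abs(rng.normal(0.0, config.inflame_heterogeneity_sd, n)), config.inflame_heterogeneity_cap))
    inflame = inflame * (lipa > 0.5)  # inflammation only after the early program

    def jumpsat(excess: np.ndarray, jump: float, sat: float) -> np.ndarray:
        return np.where(excess > 0, jump + np.minimum(excess, sat), 0.0)

    arg_nd = wp * p + severity(rng) + boost
    t_nd = config.ndstress_threshold + np.abs(rng.normal(0.0, config.ndstress_threshold_jitter_sd, n))
    s_nd = config.heterogeneity_sd
    ndstress = jumpsat(arg_nd - t_nd, config.ndstress_jump, config.ndstress_saturation)
    ndstress = ndstress * np.exp(np.clip(rng.normal(0.0, s_nd, n), -1.5 * s_nd, 1.5 * s_nd))
    ndstress = ndstress * is_dis.astype(float) * (inflame > 0.5)  # stress follows inflammation

    arg_alz = wp * p + severity(rng) + boost
    t_alz = config.alz_threshold + np.abs(rng.normal(0.0, config.alz_threshold_jitter_sd, n))
    s_alz = config.alz_heterogeneity_sd
    alz = jumpsat(arg_alz - t_alz, config.alz_jump, config.alz_saturation)
    alz = alz * np.exp(np.clip(rng.normal(0.0, s_alz, n), -1.5 * s_alz, 1.5 * s_alz)) * is_ad.astype(float)

    subjects = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject": subjects,
            "diagnosis": diagnosis,
            "age": age,
            "bioage": bioage,
            "lipa": lipa,
            "inflame": inflame,
            "ndstress": ndstress,
            "alz": alz,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return df


def _gene_structure(config: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign genes to factors and draw signed loadings."""
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    loadings = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=list(FACTORS))
    arm_sign = pd.DataFrame(0, index=loadings.index, columns=list(FACTORS), dtype=int)
    start = 0
    for factor in config.factors:
        n_f = config.n_factor_genes(factor)
        members = genes[start : start + n_f]
        start += n_f
        magnitude = config.factor_effect_sizes.get(factor, 1.0) * rng.uniform(0.8, 1.2, len(members))
        signs = np.ones(len(members))
        n_neg = int(round(config.frac_negative(factor) * len(members)))
        if n_neg:
            neg_idx = rng.choice(len(members), size=n_neg, replace=False)
            signs[neg_idx] = -1.0
        loadings.loc[members, factor] = magnitude * signs
        arm_sign.loc[members, factor] = np.sign(signs).astype(int)
    return loadings, arm_sign


def _assemble_region(
    config: CohortConfig,
    region: str,
    subjects: pd.DataFrame,
    loadings: pd.DataFrame,
    arm_sign: pd.DataFrame,
    rng: np.random.Generator,
) -> SyntheticCohort:
    latents = subjects[list(FACTORS)].copy()
    if region != config.affected_region:
        for factor in config.local_factors:
            latents[factor] = 0.0
    sample_ids = [f"{s}_{region}" for s in subjects.index]
    latents.index = pd.Index(sample_ids, name="sample_id")

    signal = loadings.to_numpy() @ latents.to_numpy().T  # genes x samples
    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd > 0 else 0.0
    values = signal + noise
    values = values - values.mean(axis=1, keepdims=True)  # gene-wise centering to cohort mean
    expr = pd.DataFrame(values, index=loadings.index.copy(), columns=latents.index)

    annotation = pd.DataFrame(
        {
            "diagnosis": subjects["diagnosis"].to_numpy(),
            "age": subjects["age"].to_numpy(),
            "region": region,
            "subject": subjects.index.to_numpy(),
        },
        index=latents.index,
    )
    thresholds = {"lipa": 0.5, "inflame": 0.5, "ndstress": 0.0, "alz": 0.0}
    truth = SyntheticTruth(
        latent_factors=latents,
        loadings=loadings.copy(),
        arm_sign=arm_sign.copy(),
        annotation=annotation.copy(),
        activation_thresholds=thresholds,
    )
    return SyntheticCohort(expression=expr, annotation=annotation, truth=truth)


def generate_multiregion(config: CohortConfig) -> list[SyntheticCohort]:
    """Generate one cohort per region with shared subjects and systemic latents.

    Systemic factors take the same per-subject latent value in every region;
    factors listed in ``config.local_factors`` are zeroed outside the
    affected region.  Only gene-level measurement noise differs by region.
    """
    config.validate_multiregion()
    ss = np.random.SeedSequence(config.seed)
    subject_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = _subject_latents(config, subject_rng)
    loadings, arm_sign = _gene_structure(config, subject_rng)
    region_seeds = ss.spawn(len(config.regions) + 1)[1:]
    cohorts = []
    for region, rseed in zip(config.regions, region_seeds):
        rng = np.random.default_rng(rseed)
        cohorts.append(_assemble_region(config, region, subjects, loadings, arm_sign, rng))
    return cohorts


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a single-region cohort (the affected region, so all five
    factors are present).  Identical config and seed give bit-identical
    output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    subject_rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = _subject_latents(config, subject_rng)
    loadings, arm_sign = _gene_structure(config, subject_rng)
    region_rng = np.random.default_rng(ss.spawn(2)[1])
    return _assemble_region(config, config.affected_region, subjects, loadings, arm_sign, region_rng)


def make_projection_target(
    cohort: SyntheticCohort,
    seed: int,
    keep_frac: float = 0.6,
    sign_flip_frac: float = 0.1,
    extra_noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...]]:
    """Re-measure a cohort on a synthetic "second platform".

    Keeps a random ``keep_frac`` subset of genes, regenerates measurement
    noise, flips the sign of a ``sign_flip_frac`` fraction of the kept
    probes (emulating mis-annotated probes with opposite regulation) and
    lower-cases the symbols (exercising case-insensitive symbol matching).

    Returns ``(target_expression, flipped_symbols, kept_symbols)`` where the
    symbol tuples are in the *target* (lower-case) spelling.
    """
    rng = np.random.default_rng(seed)
    genes = cohort.expression.index.to_numpy()
    n_keep = max(2, int(round(keep_frac * len(genes))))
    kept = np.sort(rng.choice(len(genes), size=n_keep, replace=False))
    kept_genes = genes[kept]

    latents = cohort.truth.latent_factors
    loadings = cohort.truth.loadings.loc[kept_genes]
    signal = loadings.to_numpy() @ latents.to_numpy().T
    values = signal + rng.normal(0.0, extra_noise_sd, signal.shape)

    n_flip = int(round(sign_flip_frac * n_keep))
    flip_idx = rng.choice(n_keep, size=n_flip, replace=False)
    values[flip_idx] *= -1.0
    values = values - values.mean(axis=1, keepdims=True)

    target = pd.DataFrame(values, index=[g.lower() for g in kept_genes], columns=latents.index)
    flipped = tuple(kept_genes[i].lower() for i in sorted(flip_idx))
    return target, flipped, tuple(g.lower() for g in kept_genes)
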