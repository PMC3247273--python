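"""Model/Results interface orchestrating the full biomarker analysis.

:class:`BrainAgingModel` is built from an expression matrix (genes x
samples, log10 cohort ratios) and a sample annotation table (diagnosis,
age, region, subject).  ``fit()`` runs the analysis end to end — sample QC,
BioAge construction from PC1, BioAge-matched differential expression,
supervised metagene discovery (including the early Lipa variant), biomarker
scoring and evaluation — and returns a :class:`BrainAgingResults` carrying
the scores, metagenes, diagnostics and, when ground truth from the
synthetic generator is attached, parameter-recovery metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioage as ba
from . import discovery as disc
from . import preprocess as prep
from .corestats import auroc, biomarker_score, coherence, pearson_fisher
from .datatypes import AgeModel, Metagene, PCAResult, QCReport
from .regions import assign_states, default_state_thresholds
from .synthetic import CohortConfig, SyntheticCohort, SyntheticTruth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "BrainAgingModel", "BrainAgingResults", "run_full_pipeline"]


@dataclass
class AnalysisParams:
    """Tunable thresholds of the discovery pipeline."""

    qc_components: int = 3
    qc_z_max: float = 3.0
    surrogate_min_abs_corr: float = 0.6
    matched_window: tuple[float, float] = (-0.1, 0.3)
    de_p_max: float = 0.005
    de_fc_min_log10: float = float(np.log10(1.25))
    de_fdr_max: float = 0.1
    de_equal_var: bool = True
    min_metagene_size: int = 200
    min_coherence: float = 0.75
    cluster_distance: str = "one_minus_corr"
    lipa_bioage_max: float = 0.0
    lipa_candidate_min_corr: float = 0.3

    def validate(self) -> None:
        if not 0.0 < self.surrogate_min_abs_corr <= 1.0:
            raise ValueError(f"surrogate_min_abs_corr must be in (0, 1], got {self.surrogate_min_abs_corr}")
        if not -1.0 <= self.min_coherence <= 1.0:
            raise ValueError(f"min_coherence must be in [-1, 1], got {self.min_coherence}")
        if self.min_metagene_size < 2:
            raise ValueError(f"min_metagene_size must be >= 2, got {self.min_metagene_size}")
        if not 0.0 < self.de_p_max <= 1.0 or not 0.0 < self.de_fdr_max <= 1.0:
            raise ValueError("de_p_max and de_fdr_max must be in (0, 1]")
        if self.matched_window[0] >= self.matched_window[1]:
            raise ValueError(f"matched_window must be an increasing interval, got {self.matched_window}")
        if self.qc_components < 1:
            raise ValueError("qc_components must be >= 1")


class BrainAgingModel:
    """Transcriptional brain-aging/AD biomarker model.

    Parameters
    ----------
    expression : DataFrame
        Genes x samples log10 expression ratios relative to the cohort mean.
    annotation : DataFrame
        Indexed by sample id with columns ``diagnosis`` (normal/AD/HD),
        ``age`` (years) and optionally ``region`` and ``subject``.
    params : AnalysisParams, optional
    truth : SyntheticTruth, optional
        When the data come from the synthetic generator, attaching the
        truth enables parameter-recovery evaluation in the results.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        annotation: pd.DataFrame,
        params: AnalysisParams | None = None,
        truth: SyntheticTruth | None = None,
    ) -> None:
        self.expression = expression
        self.annotation = annotation.reindex(expression.columns)
        if self.annotation["diagnosis"].isna().any():
            missing = self.annotation.index[self.annotation["diagnosis"].isna()].tolist()[:5]
            raise ValueError(f"samples without diagnosis annotation: {missing}")
        self.params = params or AnalysisParams()
        self.params.validate()
        self.truth = truth

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, params: AnalysisParams | None = None) -> "BrainAgingModel":
        return cls(cohort.expression, cohort.annotation, params=params, truth=cohort.truth)

    @classmethod
    def from_files(cls, expression_tsv, annotation_csv, params: AnalysisParams | None = None) -> "BrainAgingModel":
        from .io import read_annotation_csv, read_expression_tsv

        return cls(read_expression_tsv(expression_tsv), read_annotation_csv(annotation_csv), params=params)

    # ------------------------------------------------------------------
    def fit(self) -> "BrainAgingResults":
        p = self.params
        ann = self.annotation

        expr, qc_report = prep.remove_outliers_pca(self.expression, k=p.qc_components, z_max=p.qc_z_max)
        ann = ann.reindex(expr.columns)
        normal_mask = ann["diagnosis"] == "normal"
        ad_mask = ann["diagnosis"] == "AD"

        # --- BioAge: PC1 oriented by age in normals, surrogate metagene
        pca = ba.first_pc(expr, orient_by=ann["age"], anchor_mask=normal_mask)
        bioage_mg = ba.select_surrogate_genes(
            expr, pca.pc1, min_abs_corr=p.surrogate_min_abs_corr, name="BioAge"
        )
        bioage_mg.coherence = coherence(expr, bioage_mg)
        bioage_score = biomarker_score(expr, bioage_mg)
        age_model = ba.fit_age_model(bioage_score, ann["age"], normal_mask)

        # --- BioAge-matched differential expression and metagene discovery
        matched = disc.matched_subset(bioage_score, window=p.matched_window)
        matched = matched[ann.loc[matched, "diagnosis"].isin(["AD", "normal"])]
        de = disc.differential_expression(
            expr[matched],
            ann.loc[matched, "diagnosis"],
            p_max=p.de_p_max,
            fc_min_log10=p.de_fc_min_log10,
            fdr_max=p.de_fdr_max,
            equal_var=p.de_equal_var,
        )
        de_genes = de.index[de["passed"]]
        disease_metagenes: list[Metagene] = []
        dendrogram = None
        if len(de_genes) >= p.min_metagene_size:
            dendrogram = disc.cluster_genes(expr[matched], gene_subset=de_genes, distance=p.cluster_distance)
            disease_metagenes = disc.cut_to_metagenes(
                dendrogram,
                expr[matched],
                min_size=p.min_metagene_size,
                min_coherence=p.min_coherence,
                name_prefix="disease",
            )
            disease_metagenes = disc.rank_metagenes_by_regulation(
                disease_metagenes, expr[matched], ann.loc[matched, "diagnosis"]
            )
        else:
            logger.warning("only %d DE genes passed; skipping disease metagene discovery", len(de_genes))

        # --- early-aging (Lipa) metagene in low-BioAge normals
        try:
            lipa_mg = disc.discover_early_metagene(
                expr,
                bioage_score,
                cohort_mask=normal_mask,
                bioage_max=p.lipa_bioage_max,
                min_size=p.min_metagene_size,
                min_coherence=p.min_coherence,
                candidate_min_corr=p.lipa_candidate_min_corr,
                exclude_genes=bioage_mg.members,
            )
        except ValueError as exc:
            logger.warning("early metagene discovery skipped: %s", exc)
            lipa_mg = None

        # --- score all metagenes on the full (post-QC) cohort
        metagenes: dict[str, Metagene] = {"BioAge": bioage_mg}
        if lipa_mg is not None:
            metagenes["Lipa"] = lipa_mg
        for mg in disease_metagenes:
            metagenes[mg.name] = mg
        scores = pd.DataFrame({name: biomarker_score(expr, mg) for name, mg in metagenes.items()})

        # --- evaluation: AUROC AD vs normal, coherence by cohort, correlations
        eval_rows = []
        labels = ad_mask.astype(int)
        usable = normal_mask | ad_mask
        for name, mg in metagenes.items():
            row = {"biomarker": name, "size": mg.size}
            try:
                row["auroc_ad_vs_normal"] = auroc(scores.loc[usable, name], labels[usable]).auroc
            except ValueError:
                row["auroc_ad_vs_normal"] = np.nan
            for cohort_name, mask in (("normal", normal_mask), ("AD", ad_mask)):
                try:
                    row[f"coherence_{cohort_name}"] = coherence(expr.loc[:, mask], mg)
                except ValueError:
                    row[f"coherence_{cohort_name}"] = np.nan
            if len(de_genes):
                present = [g for g in de_genes if g in expr.index]
                row["variance_explained_de_genes"] = ba.variance_explained_by_score(
                    expr.loc[present], scores[name]
                )
            eval_rows.append(row)
        evaluation = pd.DataFrame(eval_rows).set_index("biomarker")
        score_correlations = scores.corr()

        results = BrainAgingResults(
            model=self,
            expression=expr,
            annotation=ann,
            qc_report=qc_report,
            pca=pca,
            age_model=age_model,
            metagenes=metagenes,
            de_table=de,
            matched_samples=tuple(matched),
            dendrogram=dendrogram,
            scores=scores,
            evaluation=evaluation,
            score_correlations=score_correlations,
        )
        if self.truth is not None:
            results.recovery = results._evaluate_recovery(self.truth)
        return results


@dataclass
class BrainAgingResults:
    """Fitted biomarkers, scores and diagnostics of a cohort analysis."""

    model: BrainAgingModel
    expression: pd.DataFrame
    annotation: pd.DataFrame
    qc_report: QCReport
    pca: PCAResult
    age_model: AgeModel
    metagenes: dict[str, Metagene]
    de_table: pd.DataFrame
    matched_samples: tuple[str, ...]
    dendrogram: object | None
    scores: pd.DataFrame
    evaluation: pd.DataFrame
    score_correlations: pd.DataFrame
    recovery: pd.DataFrame | None = None

    # -- derived quantities ------------------------------------------------
    def bioage_score(self) -> pd.Series:
        return self.scores["BioAge"]

    def extrapolated_age(self, target_score: float) -> float:
        return ba.extrapolate_equivalent_age(self.age_model, target_score)

    def extrapolated_age_of_mean_ad(self) -> float:
        ad = self.annotation["diagnosis"] == "AD"
        return self.extrapolated_age(float(self.bioage_score()[ad].mean()))

    def extrapolated_age_of_advanced_ad(self, quantile: float = 0.975) -> float:
        ad = self.annotation["diagnosis"] == "AD"
        return self.extrapolated_age(float(self.bioage_score()[ad].quantile(quantile)))

    def age_correlation(self, diagnosis: str = "normal"):
        mask = self.annotation["diagnosis"] == diagnosis
        return pearson_fisher(
            self.bioage_score()[mask].to_numpy(), self.annotation.loc[mask, "age"].to_numpy()
        )

    # -- parameter recovery ------------------------------------------------
    def _evaluate_recovery(self, truth: SyntheticTruth) -> pd.DataFrame:
        """Match each planted factor to its best-recovered metagene.

        A factor is matched to the discovered metagene whose score has the
        highest absolute correlation with the factor's latent values
        (BioAge and Lipa are matched by name).  For the match we report the
        score-vs-latent correlation, the membership Jaccard index against
        the planted gene set, and the arm-sign agreement (fraction of
        shared member genes whose discovered arm sign equals the planted
        loading sign, maximised over a global flip).
        """
        latents = truth.latent_factors.reindex(self.scores.index)
        rows = []
        fixed = {"bioage": "BioAge", "lipa": "Lipa"}
        for factor in truth.latent_factors.columns:
            lat = latents[factor].to_numpy()
            if np.ptp(lat) == 0:
                continue
            best_name, best_corr = None, 0.0
            if factor in fixed:
                if fixed[factor] in self.scores.columns:
                    best_name = fixed[factor]
                    best_corr = float(np.corrcoef(self.scores[best_name].to_numpy(), lat)[0, 1])
            else:
                for name in self.scores.columns:
                    if name in fixed.values():
                        continue
                    r = float(np.corrcoef(self.scores[name].to_numpy(), lat)[0, 1])
                    if abs(r) > abs(best_corr):
                        best_name, best_corr = name, r
            if best_name is None:
                rows.append({"factor": factor, "metagene": None, "score_corr": np.nan,
                             "jaccard": np.nan, "arm_agreement": np.nan})
                continue
            mg = self.metagenes[best_name]
            planted = set(truth.factor_genes(factor))
            members = set(mg.members)
            jaccard = len(planted & members) / len(planted | members) if planted | members else np.nan
            shared = planted & members
            if shared:
                truth_signs = truth.arm_sign[factor]
                agree = sum(1 for g in shared if mg.arm_sign(g) == truth_signs[g]) / len(shared)
                arm_agreement = max(agree, 1.0 - agree)
            else:
                arm_agreement = np.nan
            rows.append({
                "factor": factor,
                "metagene": best_name,
                "score_corr": abs(best_corr),
                "jaccard": jaccard,
                "arm_agreement": arm_agreement,
            })
        return pd.DataFrame(rows).set_index("factor")

    def canonical_scores(self) -> pd.DataFrame:
        """Scores renamed to the canonical factor names via the recovery
        matching (requires attached truth)."""
        if self.recovery is None:
            raise ValueError("canonical naming requires synthetic ground truth")
        mapping = {row["metagene"]: factor for factor, row in self.recovery.iterrows() if row["metagene"]}
        return self.scores[[m for m in mapping]].rename(columns=mapping)

    def progression_states(self, thresholds: dict[str, float] | None = None):
        """Assign N0-N3/A1-A2 states from canonical biomarker scores."""
        canon = self.canonical_scores()
        if thresholds is None:
            thresholds = default_state_thresholds(canon, self.annotation["diagnosis"])
        return assign_states(canon, thresholds)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        ann = self.annotation
        counts = ann["diagnosis"].value_counts().to_dict()
        lines = [
            "Brain aging / AD transcriptional biomarker analysis",
            "=" * 55,
            f"samples: {len(ann)} ({counts}); genes: {len(self.expression)}",
            f"QC removed {len(self.qc_report.removed_sample_ids)} samples "
            f"(|z| > {self.qc_report.z_max} on PC1..PC{self.qc_report.k})",
            f"PC1 variance fraction: {self.pca.variance_explained_fraction[0]:.3f}",
            f"BioAge surrogate genes: {self.metagenes['BioAge'].size} "
            f"(+{len(self.metagenes['BioAge'].positive_arm)}/-{len(self.metagenes['BioAge'].negative_arm)})",
            f"age line (normals): score = {self.age_model.intercept:+.4f} "
            f"+ {self.age_model.slope:.5f} * age  (n={self.age_model.n})",
            f"extrapolated age at mean AD BioAge: {self.extrapolated_age_of_mean_ad():.1f} y",
            f"extrapolated age at advanced AD BioAge: {self.extrapolated_age_of_advanced_ad():.1f} y",
            f"matched window samples: {len(self.matched_samples)}; "
            f"DE genes passing filters: {int(self.de_table['passed'].sum())}",
            "",
            "Biomarker evaluation:",
            self.evaluation.round(3).to_string(),
        ]
        if self.recovery is not None:
            lines += ["", "Parameter recovery vs planted truth:", self.recovery.round(3).to_string()]
        return "\n".join(lines)


# ----------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """End-to-end run configuration: either input paths or a synthetic
    cohort spec, plus analysis thresholds and an output directory."""

    output_dir: str = "metabrain_run"
    expression_tsv: str | None = None
    annotation_csv: str | None = None
    cohort: CohortConfig | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    log_level: str = "INFO"


def _digest(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(map(str, df.columns)).encode())
    return h.hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run simulate (optional) -> fit -> evaluate, persisting outputs and a
    manifest of stage records with input/output digests."""
    from .io import write_gmt

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.analysis.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"].append({"stage": stage, "elapsed_s": round(time.time() - t0, 3), **info})

    t0 = time.time()
    truth = None
    if config.cohort is not None:
        cohort_cfg = config.cohort
        cohort_cfg.seed = config.seed
        cohort = generate_cohort(cohort_cfg)
        cohort.write(out / "simulated")
        expr, ann, truth = cohort.expression, cohort.annotation, cohort.truth
        record("simulate", t0, expression_digest=_digest(expr), params=asdict(cohort_cfg))
    elif config.expression_tsv and config.annotation_csv:
        from .io import read_annotation_csv, read_expression_tsv

        expr = read_expression_tsv(config.expression_tsv)
        ann = read_annotation_csv(config.annotation_csv)
        record("load", t0, expression_digest=_digest(expr))
    else:
        raise ValueError("config needs either a cohort spec or expression/annotation paths")

    t0 = time.time()
    model = BrainAgingModel(expr, ann, params=config.analysis, truth=truth)
    results = model.fit()
    record(
        "fit", t0,
        scores_digest=_digest(results.scores),
        n_metagenes=len(results.metagenes),
        params=asdict(config.analysis),
    )

    t0 = time.time()
    results.scores.to_csv(out / "scores.csv", index_label="sample_id")
    results.evaluation.to_csv(out / "evaluation.csv")
    results.score_correlations.to_csv(out / "score_correlations.csv")
    results.de_table.to_csv(out / "de_table.csv", index_label="gene")
    write_gmt(list(results.metagenes.values()), out / "metagenes.gmt")
    if results.recovery is not None:
        results.recovery.to_csv(out / "recovery.csv")
    (out / "summary.txt").write_text(results.summary() + "\n")
    record("persist", t0, evaluation_digest=_digest(results.evaluation.fillna(-1)))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["results"] = results
    return manifest
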