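# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `metabrain`.

## Measurement model and preprocessing

Expression values are log10 ratios of each gene's intensity to the
geometric mean intensity of that gene over the samples of the same batch
(`normalize_to_cohort_mean`). The geometric mean (arithmetic mean of log
intensities) is used as the cohort reference because it makes each gene's
log-ratios sum to zero within a batch and renders the normalisation
idempotent. Masked (NaN) entries are excluded from gene means; genes
missing in more than 20% of samples are dropped with a warning.

Sample quality control standardises the scores on the first three
principal components of the gene-centered matrix and removes, in a single
non-iterative pass, every sample whose absolute z-score on any of them
exceeds 3. Genes are centered but not variance-scaled before PCA: all
values share the log-ratio scale, and scaling would inflate the weight of
noise genes. Component sign is irrelevant here because only |z| is used.

## BioAge

PC1 of the gene-centered matrix is computed by full SVD and its sign fixed
so that the component correlates non-negatively with chronological age
over the non-demented samples. The reported BioAge biomarker is not the
raw PC1 projection but the score of a surrogate metagene — genes with
|Pearson ρ| ≥ 0.6 against PC1, split by sign into positive and negative
arms — so that the biomarker is a gene set that can be matched onto other
platforms. The threshold is exposed (`surrogate_min_abs_corr`); a
top-N-per-sign rule is available as an alternative.

The age model is an ordinary least-squares line of BioAge score on
chronological age over the normal cohort only. Equivalent-age
extrapolation inverts this line: `age(score) = (score − intercept)/slope`.
The extrapolation is linear by design; only the linear endpoints are
quantified.

"Variance explained" by a score over a gene subset is the per-gene R²
aggregation `Σ_g r_g² var_g / Σ_g var_g` — the variance captured by
regressing each gene on the score, relative to the subset's total
variance. This definition (rather than projection variance) is recorded
here because the two differ when the score is not a principal component of
the subset.

## Metagene discovery

Disease metagenes are found supervised. Samples with matched moderate
BioAge (score in the closed interval [−0.1, 0.3] by default) are selected
so that the AD-vs-normal contrast is not dominated by the aging axis.
Differential expression uses a two-group pooled-variance t-test (the
two-group ANOVA; Welch is a switch), a fold-change filter on the log10
scale (|Δ| > log10 1.25, i.e. "more than 25%"), and Benjamini-Hochberg
FDR < 0.1 computed over all tested genes. Genes with (near) zero
within-group variance receive p = 1 when the group means agree and a
variance-floored (1e-12) statistic otherwise, with a logged warning.

Passing genes are clustered agglomeratively with average linkage on the
correlation distance d = 1 − ρ (a `one_minus_abs_corr` switch exists).
Average linkage is the standard companion of correlation distance in
coexpression analysis. The dendrogram cut proceeds in two steps:

1. **Branch collection.** Top-down, the most inclusive branches whose
   plain coherence reaches `min_coherence` (default 0.75) and whose size
   is at least `min_size // 4` are collected; descendants of an accepted
   branch are suppressed. A *split-refinement* rule guards against
   lumping: if a child branch (of qualifying size) is more than 0.04 more
   coherent than its parent, descent continues instead of accepting the
   parent. For a homogeneous cluster the children improve on the parent
   only marginally, so genuine metagenes are not split; the rule fires
   when a barely-qualifying branch actually contains two distinct tight
   clusters.
2. **Arm reunification and trimming.** Under d = 1 − ρ the two
   anti-correlated arms of a two-arm metagene lie on opposite ends of the
   tree, so a two-arm metagene never exists as a single branch. Branch
   pairs whose mean profiles correlate at or below −`min_coherence` are
   merged into two-arm metagenes (most anti-correlated pairs first),
   provided the merged, arm-corrected metagene still reaches the size and
   coherence bars. Finally, member genes whose arm-corrected correlation
   with the metagene mean falls below `min_coherence / 2` are trimmed:
   a large tight cluster can otherwise chain uncorrelated hangers-on
   while its average coherence stays above threshold.

Arms are assigned by a two-pass sign rule: genes are signed by correlation
with the raw mean profile, then re-signed against the arm-corrected mean;
orientation is fixed so the positive arm is the larger (ties broken toward
the arm holding the lexicographically smallest symbol). Metagene size
defaults to ≥ 200 genes, operationalising "several hundred". Discovered
metagenes are ranked by the between-group variance of their scores (most
regulated first); the ranking rule is recorded in the output.

The early (Lipa-like) metagene is discovered among candidate genes
upregulated with BioAge (ρ ≥ 0.2 over normals, excluding genes already
claimed by the BioAge surrogate), clustered over the normal samples with
BioAge ≤ 0. In that range-restricted stratum the global aging axis has
little variance while an early-activating factor still spans its dynamic
range. Among qualifying branches the *most coherent* metagene is returned
— the early program is identified by its exceptionally high mutual
correlation, not by its size.

## Scoring and statistics

The biomarker score is the mean log-ratio over positive-arm genes minus
the mean over negative-arm genes; per-sample missing entries are excluded
by re-averaging, and a warning is logged when over half an arm is absent.
Coherence is the mean Pearson correlation of arm-corrected member genes
with the metagene's mean profile. Correlation significance uses the
Fisher z-transform, `z = atanh(ρ)·√(n−3)`, against the standard normal
(two-sided). AUROC is the Mann-Whitney rank statistic (ties count one
half), computed by rank rather than threshold sweep because the two are
identical and the rank form has fewer edge cases. Gene-set overlap uses
the hypergeometric upper tail with optional Bonferroni correction;
curated gene-set content is user-supplied (GMT).

## Cross-platform projection

Metagene symbols are matched case-insensitively against the target matrix
(many-to-one probe-to-symbol matches keep all probes; alias resolution is
out of scope). A provisional score is computed from all matched probes
with their original arm signs; probes whose arm-adjusted correlation with
that provisional score is negative — opposite regulation by sign — are
dropped in a single refinement pass (iteration to a fixed point is behind
a flag), and the score is recomputed. Projected scores are validated
against an endpoint by Fisher-z correlation plus an expected-direction
check.

## Regions and progression states

Systemic-vs-localized structure is quantified by Fisher-z correlation of
per-subject biomarker scores between brain regions, pairing only subjects
present in both. The biomarker ordering claim — inflammation precedes
neurodegenerative stress — is operationalised as quadrant emptiness: the
count of samples with NdStress above and Inflame below their thresholds,
with a Monte-Carlo permutation null for the probability of a count at
least as small under random re-pairing.

States are assigned per sample by precedence: A2 (Alz high; an A1 co-flag
is recorded when NdStress is also high, since a brain may reach A2 by a
different path) > A1 (NdStress high) > N3/N2 (Inflame high, split by a
BioAge threshold defaulting to the AD-cohort median) > N1 (Lipa high) >
N0. "High" defaults to the top-tercile boundary per biomarker and is
fully configurable; the assignment is deterministic and total over finite
scores. States are assigned per (sample, region) without cross-region
reconciliation.

## The synthetic cohort generator

The generator is first-class, tested code: it plants exactly the latent
structure the pipeline assumes and emits the ground truth (latent factor
values per sample, signed loadings and arm signs per gene, activation
thresholds) needed for parameter-recovery testing.

**Subjects.** Default 200 normal, 100 AD, 50 HD subjects, ages uniform on
60–95 y (65–95 y for disease). The bioage latent of a normal subject is
`0.01·(age − 60)` plus N(0, 0.15) individual scatter; for AD it is
N(0.40, 0.20) *independent of age* (HD: N(0.35, 0.20)), with draws below
0.15 reflected upward — diseased brains never present with low biological
age. These scales reproduce the equivalent-age arithmetic (average AD ≈
100 y, advanced AD ≈ 140 y on the normal trend) by construction.

**Latent factors and ordering.** A progression axis `p = bioage + jitter`
drives the early factor: `lipa = sigmoid((p + 0.05)/0.1) · exp|N(0,0.4)|`.
The three disease factors run on arguments `0.25·p + severity + boost`,
each with its *own* severity draw (sd 0.12 in normals, 0.25 in disease)
and disease boost (0.45 for inflame, 0.32 for ndstress/alz), and are
**hierarchically gated**: inflame is zeroed unless lipa exceeds its
half-activation point, and ndstress is zeroed unless inflame does.
Gating makes the activation ordering lipa → inflame → ndstress exact for
every seed — the (NdStress-high, Inflame-low) quadrant is empty by
construction — while the per-factor severity draws keep the factors
mutually resolvable by clustering. The lipa amplitude multiplier is ≥ 1
so heterogeneity can never undo a gate condition. Ndstress and alz have
switch-like responses — a jump at onset, then growth saturating 0.25
above threshold — times a clipped lognormal severity multiplier; the
saturation concentrates the disease contrast at moderate progression
(where the matched-BioAge window sits) instead of in a long high-severity
tail. A random 10% of non-demented brains carry age-independent
inflammation (gated on lipa-active progression), emulating infection or
injury. Ndstress is active in both AD and HD; alz only in AD and only in
the affected region (default PFC of a PFC/VC pair); all other factors are
systemic, taking identical per-subject values in every region with only
gene-level measurement noise differing.

**Genes.** 3000 genes: 600 load on bioage (half negated — the
down-with-age arm), 300 each on lipa/inflame/ndstress (40% of ndstress
genes negated, giving its two arms), 300 on alz, the rest pure noise.
Per-gene loading magnitudes are the factor effect size times U(0.8, 1.2);
gene-level noise is homoscedastic Gaussian (sd 0.06) on the log10 scale,
matching the log-ratio measurement model and keeping Pearson-correlation
theory exact. Expression is gene-wise centered to the cohort mean.

**Calibration.** The brain-aging narrative fixes the qualitative
structure and a few scales (the 0.01/yr age line, the high-mean
age-independent disease bioage); everything else — effect sizes, noise,
thresholds, heterogeneity — was chosen once, at design time, so that the
planted factors are strong enough to satisfy the pipeline's own discovery
thresholds (per-gene coherence well above 0.75; matched-window fold
changes comfortably above the 25% filter) while remaining mutually
separable (each non-aging factor's full-cohort correlation with the
aging axis below the 0.6 surrogate-selection threshold). The generator
defaults *are* the study conditions used by the test-suite and the
acceptance script.

**What the generator does not emulate.** Probe-level artefacts, batch
effects between profiling phases, longitudinal sampling, alias/symbol
ambiguity, non-Gaussian heavy-tailed measurement noise, and any realistic
gene-gene correlation beyond the planted factors. Passing recovery tests
therefore demonstrates that the pipeline's machinery is correct and
internally consistent under its own assumptions — not that real brain
cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

SVD-based PCA throughout (no iterative solvers); constant matrices raise
"no variance". A constant orientation anchor leaves PC1 unflipped with a
logged warning. Correlations of constant vectors raise rather than
returning NaN. Fisher-z p-values are clamped to (0, 1]. The permutation
p-value uses the (k+1)/(N+1) estimator. Dendrogram distances are
symmetrised and clipped at 0 before linkage. All randomness flows from a
single integer seed via `numpy.random.SeedSequence` spawning, so
identical configurations reproduce bit-identical cohorts and digests.

## Problem sizes

The test-suite and acceptance script run the full pipeline on five
replicate cohorts of 350 subjects × 3000 genes — the study-scale
conditions described above — which completes in seconds per cohort.
Oracle-equivalence checks use 100 random instances for AUROC and BH, 50
random 20×15 matrices for PC1 and exhaustive enumeration for
hypergeometric universes up to 30.

## Known limitations

* The HD-vs-normal AUROC of the Alz biomarker is a noise-only statistic
  with Monte-Carlo sd ≈ 0.05 at these group sizes; single cohorts can
  stray ~0.1 from 0.5, so the acceptance script reports the mean over
  replicate cohorts.
* True alz latents are exactly zero outside the affected region, so
  truth-level cross-region correlation of alz is undefined; the
  systemic-vs-localized comparison uses measured scores.
* The progression-state model is cross-sectional and descriptive: no
  transition rates are fitted, and the thresholds that define "high" are
  conventions (terciles or generator activation levels), not estimates.
* Metagene discovery assumes several-hundred-gene factors; factors
  smaller than `min_size` after differential-expression recall are
  invisible by design.
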