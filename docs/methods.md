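# Methods

This note documents the statistical procedures `wntstrat` implements, the
defaults it ships, the design choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Problem setting

Bulk expression profiles of primary breast tumors are collected across
several studies on different platforms (different gene panels, per-gene
location/scale behavior). The analysis asks three questions: (i) is
transcriptional Wnt/β-catenin activity elevated in the triple-negative (TN)
subtype, (ii) can a classifier trained on an oncogene-perturbation
experiment (β-catenin-transfected mammary epithelial cells vs control and
other oncogene models) be transferred to tumor cohorts to call a Wnt+
state, and (iii) do Wnt+ tumors carry excess risk of site-specific
metastasis (lung, brain) but not bone.

## Preprocessing conventions

- **Quantile normalization** within a cohort: every sample's sorted values
  are replaced by the across-sample mean of sorted values. Ties within a
  sample receive the mean of the reference values of their tied ranks — a
  deterministic dialect chosen so that repeated application is a fixed
  point and column permutation commutes with the transform. Genes with any
  missing value in a cohort are dropped from that cohort first (count
  logged); nothing is imputed.
- **Technical replicates** are mean-combined into one column per specimen
  after normalization.
- **Linear-intensity arrays** are rescaled per sample so the 2%-trimmed
  mean equals a common target intensity (default 600). Log2-scale input
  skips this step.
- **"Normalized" for pathway scores** means a per-gene z-score across
  samples *within one cohort* (population SD; constant genes become zero
  rows). Z-scores are never pooled across cohorts, because platforms
  differ; this is also what makes classifier transfer invariant to
  per-gene affine platform distortions.
- **Cross-study harmonization**: specimens duplicated between studies are
  kept in the first study (input order) only; a pooled analysis may
  additionally restrict all cohorts to the common gene intersection. Gene
  identity is the upper-cased symbol; when several probes collapse to one
  symbol the row with maximal mean intensity is kept (a common convention;
  the choice matters little for mean-based scores).
- **Hierarchical clustering** (for heatmap-style displays) is Euclidean,
  complete linkage. Items are pre-sorted lexicographically by id before
  linkage so tie-breaking is deterministic; both choices are config knobs,
  not claims about any particular published figure.

## Differential expression

Two-group comparison on log2 expression uses the moderated statistic

    d_i = (mean_A − mean_B) / (s_i · c + s0),   c = √(1/n_A + 1/n_B),

with s_i the pooled within-group SD and fudge factor s0 = median_i (s_i·c),
which keeps near-zero-variance genes from dominating. Significance comes
from label permutations (all distinct assignments when there are at most B
of them, otherwise B sampled): the FDR at cut t is

    FDR(t) = mean_b #{|d*_b| ≥ t} / #{|d| ≥ t},

and a gene's q-value is the minimum FDR over all cuts t ≤ |d_i|, clipped to
[0, 1] — the standard q-value construction, monotone non-increasing in
|d|. The **mean** (not median) of permuted exceedance counts is used: with
a few hundred genes the median count at the most extreme cuts is exactly
zero in a large fraction of pure-null datasets, which would assign the
top-ranked genes q = 0 and destroy type-I-error control; the mean — the
estimator of the original significance-analysis-of-microarrays
formulation — stays positive once any permutation exceeds the cut. No π0
correction is applied, which is conservative. Calls additionally require a
linear fold change of at least 1.5 (|log2FC| ≥ log2 1.5); defaults are
FDR ≤ 1% and FC ≥ 1.5.

## Pathway scores and tests

The canonical pathway score is the mean z-score over the pathway genes
present on the panel (coverage recorded; an absent pathway scores NA). The
oncogenic signed score is (Σ induced z − Σ inhibited z) / (members on
panel), so induced genes weigh positively and inhibited genes negatively.
Overrepresentation of a gene set among DE genes is the one-sided
hypergeometric upper tail on the 2×2 (in-set × DE) table with the platform
panel as universe, Bonferroni-corrected across tested sets. Differential
pathway regulation between subtypes uses a Welch t-test (robust to unequal
variances; whether the original analyses pooled variances is unknowable
from the text, so the robust choice is documented) with Bonferroni
correction over pathway × contrast pairs, plus a label-permutation p with
the +1 correction so permutation p-values are never zero.

## The Wnt classifier

Nearest shrunken centroids: per-gene class offsets

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n),

(m_k is the SD factor of a class mean compared against an overall mean that
contains the class), soft-thresholded d′_ik = sign(d)·max(|d|−Δ, 0), with
shrunken centroids x̄′_ik = x̄_i + m_k (s_i + s0) d′_ik. Classification
minimizes δ_k(x) = Σ (x_i − x̄′_ik)²/(s_i+s0)² − 2 log π_k over the genes
shared between model and cohort; posteriors are softmax(−δ/2).

Training is binary: class "Wnt" = the β-catenin perturbation samples,
class "other" = controls pooled with the remaining oncogene models (E2F3,
Myc, Ras, Src), because the downstream output is a two-state Wnt+/Wnt−
call. Priors default to uniform — the pooled "other" class is artificially
large, so empirical priors would encode an artifact of the pooling, not
tumor biology (empirical priors remain available). Δ is chosen by
stratified K-fold cross-validation (default 5 folds) as the **largest** Δ
tying the minimum CV error, preferring the sparsest equally good model.
Transfer to a tumor cohort z-scores the cohort within itself, refits the
model on z-scored training data restricted to the shared genes (same Δ and
priors), and refuses cohorts sharing fewer than 20% of model genes.
Missing model genes are dropped from the discriminant sum, never imputed.
The original study's Δ, priors and gene filtering are not recoverable from
its text; all are explicit configuration here, and results are reported
per configuration rather than claimed to replicate any published count.

## Clinical association

Wnt calls are crossed with pathological subtype, intrinsic subtype, grade
(1/2/3) and node status; samples missing either dimension are excluded
with a logged count. 2×2 tables use Fisher's exact test (two-sided = sum
of hypergeometric point masses ≤ the observed mass; a zero margin returns
p = 1). 2×K tables use the Freeman–Halton extension: exact enumeration of
all first-row vectors compatible with the margins for totals ≤ 200 (with
an internal cap of 5·10⁵ tables, since K ≥ 4 at N = 200 can explode
combinatorially), otherwise a fixed-margin Monte-Carlo estimate
(multivariate hypergeometric sampling, default 10⁵ replicates, +1
correction). Subtype association is reported both as the full 2×K table
and collapsed to TN-vs-other (resp. basal-vs-other) 2×2. Two-sided
alternatives are the default throughout.

## Survival

Kaplan–Meier curves use the product-limit estimator (via lifelines) with
Greenwood variance; ties follow the events-before-censoring convention (a
subject censored at t is still at risk at t). The two-group log-rank test
accumulates observed and expected events and the hypergeometric variance
over the combined lifetable, so the reported O_g, E_g and V are the actual
accumulated quantities; the statistic is (O−E)²/V against χ²(1). The
implementation is cross-checked against lifelines' log-rank test in the
suite. Site-specific metastasis-free survival is cause-specific:
metastases at other sites are censored at their event time (no
competing-risks cumulative incidence, matching the Kaplan–Meier framing of
the emulated analyses). Records with zero total events raise an
informative error; a single group with zero observed events is permitted
(O = 0 is well-defined) — requiring an event in *every* group would
spuriously reject valid strongly-separated data.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so that every downstream stage has a
measurable truth:

- **Perturbation training set**: i.i.d. N(0,1) log2 baseline; control plus
  five oncogene classes with replicates (default 10/class); each oncogene
  gets a disjoint signed signature (default 30 induced and 30 inhibited
  genes) shifted by ±`pathway_effect` (default 1.5 SD).
- **Tumor cohorts** (default 5 × 60 samples, 1000 genes): subtypes drawn
  HR+/HER2+/TN at (0.55, 0.15, 0.30); a latent Wnt state with
  P(Wnt+|TN) = 0.6 and P(Wnt+|other) = 0.02, giving ≈ 19% Wnt+ overall —
  an intentionally TN-concentrated activation pattern; Wnt+ tumors have
  the β-catenin signature shifted by the same effect size. Each cohort has
  its own panel (a core sized by `panel_overlap_fraction` = 0.7 that
  always contains the signature genes, plus a random half of the
  remainder), its own per-gene affine distortion (slope U[0.8, 1.2],
  offset U[−0.5, 0.5]) — the minimal structure that makes per-cohort
  standardization necessary and testable — technical replicate columns
  (10% of specimens), and optionally specimens duplicated into the next
  cohort to exercise duplicate removal.
- **Clinical covariates** correlated with Wnt state: grade probabilities
  (1, 2, 3) of (0.05, 0.25, 0.70) for Wnt+ vs (0.25, 0.45, 0.30) for
  Wnt−, and node-positivity 0.55 vs 0.45 — a strong grade gradient and a
  deliberately weak node association, mirroring the shape of the emulated
  clinical findings.
- **Survival**: each endpoint is generated independently (OS, RFS, MFS) as
  exponential times — the emulated analyses treat endpoints marginally, so
  no multistate process is modeled. MFS is a competing-site construction:
  per-site latent exponential times with baseline hazard 0.02/month split
  across sites, the earliest site wins. Default site weights are lung
  0.35, brain 0.35, bone 0.20, other 0.10, and default hazard ratios for
  Wnt+ are 2.5 (lung), 2.5 (brain), 1.0 (bone, other), 1.5 (OS, RFS).
  Censoring is independent U(0, b) per endpoint with b solved numerically
  so the expected censored fraction matches `censor_rate` (default 0.15)
  under the baseline hazard. The lung/brain weights exceed and the bone
  weight undercuts real metastasis registries (where bone is the most
  common site); they were fixed a priori by Schoenfeld power arithmetic so
  that a cohort of 400 patients yields roughly 110–130 events per
  Wnt-sensitive site, enough for the planted lung/brain effect to be
  detectable while bone stays null. Simulations at other sizes should
  revisit these weights.

Not emulated: probe-level physics, batch/chip effects, gene–gene
correlation beyond the planted signatures, multistate or informative
censoring, subtype-specific expression beyond the Wnt latent. Passing
tests therefore demonstrate correctness of the estimators and the
transfer machinery under the declared assumptions — not robustness to
correlated noise, batch structure, or misspecified survival models in
real cohorts.

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; a fixed seed yields byte-identical outputs. The pipeline
derives each stage's seed as SHA-256(master seed, stage name) mod 2³¹ so
that changing one stage's parameters never perturbs another stage's
random stream.

## Numerical choices and degenerate inputs

- Quantile normalization of a single-column matrix returns it unchanged
  (warning); z-scoring constant genes yields zero rows (warning).
- The fudge terms s0 (DE statistic, NSC) are medians of per-gene scale
  estimates; they keep zero-variance genes finite and are recomputed per
  permutation in the permutation null.
- Permutation p-values carry the +1 correction; exact-test p-values are
  clipped to (0, 1]; two-sided mass comparisons use a 1e−9 relative
  tolerance to absorb floating-point ties.
- CV fold counts are reduced (with a warning) when a class is smaller than
  the requested fold count; a class with fewer than 2 samples is an error.
- Problem sizes in the test suite and acceptance script (e.g. 50-seed
  Monte-Carlo batches, 200-gene null panels, 400-patient survival cohorts)
  were chosen as the smallest sizes at which the targeted effects are
  comfortably identifiable by a priori power arithmetic.

## Known limitations

- The permutation FDR has no π0 correction (conservative for signal-rich
  panels).
- The Freeman–Halton exact route can fall back to Monte-Carlo below the
  N ≤ 200 threshold when the margin structure makes enumeration explode;
  the fallback is logged.
- Transfer assumes gene symbols harmonize across platforms; no ortholog or
  probe-level mapping is attempted.
- Survival analyses are univariate log-rank comparisons; no Cox models or
  covariate adjustment.
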