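# Methods

This package implements a type 1 diabetes (T1D) genetic-risk analysis as a
tested pipeline over synthetic cohorts: penalized logistic association and
meta-analysis with conditional signal discovery, approximate-Bayes-factor
fine-mapping, a gradient-boosted genetic risk score with linear and additive
baselines, SHAP-based interaction discovery and complexity scoring, and
SHAP-space subtyping with clinical contrasts. Everything below is the
package's own account of what it computes and why; no empirical number is
stated here that the tests or `scripts/acceptance.py` do not themselves
compute.

## Synthetic cohort generator

The generator is first-class code, not a fixture: it defines the study
conditions every downstream claim is tested under.

**Genotypes.** Diploid dosages (0/1/2) over a ~200-variant panel. Each
individual is the sum of two haplotypes; within an LD block, haplotype
alleles come from an AR(1) Gaussian copula (parameter `ld_rho`, default 0.7)
thresholded at each variant's allele-frequency quantile. This gives exact
marginal MAFs and monotonically controllable pairwise r² without a haplotype
reference panel. Thresholding attenuates the latent correlation, so genotype
r² is below `ld_rho²` (e.g. latent 0.95 gives genotype r² ≈ 0.6); tests that
need near-perfect proxies use latent values ≳0.998.

**MHC analog.** A three-class haplotype system {DR3, DR4, X} with population
frequencies 0.15/0.15/0.70, drawn per-individual as two independent
haplotypes (Hardy–Weinberg). Tag variants carry the haplotype copy number as
their dosage. Risk enters as a per-copy log-OR (ln 3 per DR3 or DR4 copy by
default) plus a heterozygote bonus applied only to the DR3/DR4 diplotype,
sized so that the heterozygote class sits at a 16-fold odds ratio against the
no-DR3/DR4 class — the hallmark super-additive risk of that genotype.

**Disease model.** Binary labels from a logistic model:
intercept + per-variant additive log-ORs + pairwise epistatic terms
(dosage-product encoding by default; carrier-indicator optional, recorded in
the truth record) + the heterozygote bonus + covariate effects (sex, PC1).
Default additive architecture: per-copy ln 3 on the two haplotype tags,
independent MHC signals ~ N(0, 0.6²) on the remaining MHC-analog variants
(echoing the many conditional class I/II signals of the region), and a
genome-wide polygenic background ~ N(0, 0.18²). These defaults place the
generator's Bayes-optimal discrimination near the performance regime the
analysis is designed for (AUC ≈ 0.92 at the default panel). The intercept is
centered analytically — expected genetic contribution subtracted, with a
logistic-normal variance correction `mu = logit(p)·sqrt(1 + 0.346·Var(eta))`
— targeting a case-enriched prevalence of 0.34 (≈1 case : 2 controls, the
usual composition of combined case-control panels); the realized prevalence
is within a few points of the target because the correction ignores
interaction and covariate variance.

**Clinical outcomes.** Each case carries a planted subtype; onset age is
truncated-normal (at zero) with per-subtype location/scale in years, and each
complication (nephropathy, neuropathy, CVD, retinopathy) is Bernoulli with a
per-subtype multiplier applied on the odds scale to a baseline probability.
The default clinical spec gives the late-onset "pancreas-like" subtype
elevated complication odds (1.29/1.35/1.46-fold) — a direct generative link
from subtype to complication; whether that link is direct or mediated (e.g.
by glycemia) is not modeled, and the truth record says so.

**Interaction-experiment conditions.** Two dedicated architectures exist
because the general generator is *not* interaction-free even with no planted
epistasis:

- Block LD between model features creates genuine tree-model interactions
  (substitution effects between correlated features). The model-facing panel
  emulates LD-clumped lead variants, so interaction experiments use linkage
  equilibrium (`ld_rho = 0`).
- The diplotype constraint (DR3 copies + DR4 copies ≤ 2) makes even a
  bonus-free MHC non-additive over the feature support.

`interaction_discovery_effects` plants a single multiplicative MHC × non-MHC
pair (log-OR 0.7 by default) between common variants (both MAFs ≥ 0.2) over
moderate additive effects; `additive_null_effects` is the strictly additive
null: every variant gets a moderate additive effect (SD 0.25), no pairs, no
haplotype classes.

**Determinism.** One master seed; every stochastic operation derives a child
seed as `sha256(master:op-name) mod 2³¹`, so stages are independently
reproducible and a cohort regenerates bit-identically from its truth record.

## Association and meta-analysis

Firth (Jeffreys-prior penalized) logistic regression is hand-implemented
(no installed package provides it): Newton iterations on the modified score
`Xᵀ(y − p + h(½ − p))` with hat-matrix leverages `h`, tolerance 1e-8 on the
score norm, at most 100 iterations, step-halving on penalized-likelihood
decrease. Standard errors come from the inverse Fisher information at the
optimum; p-values are two-sided Wald. The penalty keeps estimates finite
under complete separation — the regime rare large-effect variants live in.
Zero-variance dosages and rank-deficient covariates are rejected with the
offending columns named (a greedy QR scan identifies a minimal collinear
set).

Meta-analysis is fixed-effects inverse-variance weighting:
`beta = Σw·b/Σw`, `se = (Σw)^-1/2`, `w = se⁻²`. Clumping follows the
two-round greedy scheme (round 1: index p < 5e-8, members p < 0.05, r² > 0.1,
window 10 Mb; round 2: indices re-clumped at any nonzero r² within 500 kb),
and each final locus spans ±500 kb of its index. Stepwise conditional
discovery adds the most significant variant's dosage to the covariates and
re-runs the per-cohort Firth + meta loop until the minimum p reaches 5e-8;
ties break by smallest p, then largest |z|, then variant id, so reruns are
deterministic. Preconditioning covariates (e.g. 70 allele dosages + 20
binary both-carrier interaction columns) can be supplied to expose signals
masked by known alleles. MAF filters are configuration constants: 1% for
MHC-region scans, 0.1% genome-wide. All betas are reported for the VCF alt
allele; risk-direction flipping happens only in the risk-model module.

For scans where the penalty is unnecessary (common variants, moderate
effects — e.g. the fine-mapping calibration harness), `logistic_scan` runs
vectorized two-parameter Newton fits across variants.

## Wakefield fine-mapping

For a single signal, the linkage set is every variant with r² > 0.1 to the
lead. Evidence per variant is the reciprocal Wakefield approximate Bayes
factor `BF = sqrt(V/(V+W))·exp(z²W/(2(V+W)))` (V = se², z = beta/se),
oriented so larger = more associated. W, the prior variance of the log-OR
under the alternative, is unstated in the source analysis; the default is
0.04 (prior SD 0.2), a standard binary-trait choice, exposed in config and
echoed in output headers. PIPs are BFs normalized over the set; the 95%
credible set is the smallest descending-PIP prefix reaching 0.95 (the
crossing variant included; ties in PIP break by variant id).

The coverage harness plants one causal variant per simulated region with
log-OR ~ N(0, W), fits per-variant logistic scans and measures how often the
95% set contains the causal variant. PIPs are normalized over the whole
region by default: normalizing over the linkage set of a noisy max-|z| lead
is not calibrated when the causal effect is weak, because the causal variant
can fall outside the lead's linkage set (the production `restrict_linkage`
construction is available and is conservative only when lead and causal are
linked). Under matched priors the greedy ≥-mass rule overshoots the nominal
level, so empirical coverage at 0.95 is expected at or above 95%; a
misspecified-W mode reports coverage under a 10× wrong prior.

## Risk model

Features are risk-oriented dosages (d′ = 2 − d when the reference beta is
negative) for the MHC panel, the non-MHC panel or both, optionally plus sex,
four genotype PCs and cohort dummies. The primary model is a gradient-boosted
decision-tree classifier — xgboost is the backend — with 254 trees, depth 5,
learning rate 0.12, scored under stratified 10-fold cross-validation: each
individual's score comes from the fold model that never saw them, and a
representative full-data model is kept for attribution. The baselines are an
L2-regularized logistic regression (C = 0.001) under the identical fold
split, and a generic additive GRS engine (weighted dosage sum plus optional
diplotype-class terms). Probability outputs are reported as scores, not
calibrated probabilities.

Evaluation: AUC and average precision; the paired DeLong test from placement
values (midrank construction, degenerate zero-variance differences give
p = 1); per-stratum McNemar contrasts of false-negative (cases) and
false-positive (controls) rates across MHC diplotype classes — exact
two-sided binomial when the discordant count is ≤ 10, continuity-corrected
χ² otherwise; and a Youden scale whose thresholds are nearest-rank centiles
of the case score distribution (grid {5,10,…,50,75,95}), reporting
sensitivity, specificity, the control centile and J = sens + spec − 1.

## SHAP interpretation

Attributions are exact TreeSHAP values computed natively by the tree
library on the margin (log-odds) scale, where the additive decomposition is
exact; out-of-fold by default (each individual attributed by the model that
did not train on them). Local accuracy (base + Σφ = margin) holds to
float32 precision (~1e-4 absolute), and a closed-form single-stump oracle
(leaf value minus cover-weighted expectation) validates the library
contract. Pairwise SHAP interaction tensors are symmetric with main effects
on the diagonal and row sums reproducing φ; they cost ~2·F contribution
passes per individual, so large cohorts are subsampled (default 2,000
individuals) — the downstream statistic is a mean over individuals, so
subsampling only widens Monte-Carlo error.

Interaction significance: each unordered pair's statistic is the mean over
individuals of |Φ_ij + Φ_ji|; |Φ| rather than signed Φ so protective and
risk interactions both register (the signed mean is reported alongside).
z-scores compare each pair against the cross-pair background distribution,
by default on the log scale: the linear-scale background is strongly
right-skewed — its spread tracks the strength of the features involved — and
flags strong-feature pairs under purely additive generators (measured as a
systematic anti-conservative bias), while the log-scale version satisfies
the suite's FDR-control checks. Two-sided normal p-values are
Benjamini–Hochberg corrected; discovery flags require both q below threshold
(0.05 and 0.10 both reported) and positive z. A per-pair mode (z-testing
each pair's signed values across individuals) is available. Pairs are
categorized MHC–MHC / MHC–nonMHC / nonMHC–nonMHC (covariates count with
non-MHC).

Complexity is the total displacement `C = Σ|φ|` per individual, with decile
assignment balanced to within one; per-decile AUC with DeLong contrasts
quantifies where the nonlinear model's advantage concentrates. Component
attribution sums φ over feature groups per stratum with a one-sample
two-tailed t-test. 2-D partial dependence clamps a feature pair to the
{0,1,2} grid and averages the model margin; the corner double-difference
(f₂₂ − f₂₀ − f₀₂ + f₀₀) is zero for additive surfaces.

## Subtyping

Case attribution vectors are centered and reduced by PCA (up to 175
components), connected in a Euclidean kNN graph (k = 120, capped at n − 1)
and clustered by Leiden community detection (RB-configuration quality,
resolution 0.05); labels are canonicalized by descending cluster size. The
cluster count is checked by a resolution sweep scored with silhouette (PC
space) and within-cluster inertia; k = 1 solutions carry no silhouette and
are excluded. A UMAP layout (min_dist 0.25) is presentation-only — no
statistic depends on its geometry beyond separation ratios. Validation
cohorts are projected with the discovery PCA loadings and assigned by
majority vote of their k nearest discovery neighbors (ties to the nearest
neighbor), a deterministic, library-independent contract; per-cluster
centroid distances are reported.

Characterization: per cluster × feature, log2 fold-change of mean |SHAP|
inside vs outside (absolute values keep ratios well-defined when mean signed
attributions cross zero) with Welch t-tests on the raw attributions, raw and
BH-adjusted p both reported (whether the original analysis corrected these
is unstated). Top loci per cluster are features whose cluster share of mean
|SHAP| (normalized to sum to 1 across clusters) exceeds 0.75 — uniqueness is
guaranteed above 0.5. Cell-type enrichment sums credible-set PIPs of the
cluster's top loci per cell type and permutes the full annotation table's
cell-type labels (10,000 times by default) with the add-one estimator, so p
is never below 1/(n_perm+1); permuting only within a cluster's own variants
degenerates when they share one annotation, which is why the null is global.
Onset contrasts use the multivariate log-rank test (onset treated as fully
observed); complications use cluster-vs-rest 2×2 odds ratios with Woolf CIs
(Haldane 0.5 correction on zero cells, flagged), Fisher exact p, and an
optional Cox proportional-hazards p when onset times are supplied. T2D-locus
enrichment regresses the binary T2D label on per-cluster attribution shares;
Firth regression is used because tens of loci with near-degenerate shares
frequently quasi-separate.

## Pipeline

`run_pipeline` executes simulate → assoc → finemap → train → interpret →
subtype from one validated config (unknown keys and invalid values rejected
by name before any stage runs), each stage writing serialized outputs (VCF /
TSV / JSON) before the next starts, with a manifest of SHA-256 output
hashes, timings and library versions. Stages communicate only through those
serialized interfaces plus documented in-memory handles; deterministic
stages reproduce identical hashes under the same config and seed.

## Problem sizes used by the test suite

Chosen as desk-scale versions of the analysis, stated here as package
choices: association/conditional tests use cohorts of 4,000–20,000;
planted-OR recovery uses n = 40,000 (class OR 16) and n = 100,000 (rare OR
2.8, MAF 0.0015), with `scripts/acceptance.py` combining 6 and 10 such
cohorts respectively by IVW meta-analysis to shrink Monte-Carlo error around
the planted values; coverage calibration runs 1,000 regions of 30 variants
at n = 4,000; interaction discovery runs 25 power replicates (16-variant
common panel, n = 10,000, 600-individual tensors) and 10 additive-null
replicates (300-individual tensors); model-ordering runs n = 10,000 with
four planted pairs; subtype recovery uses 1,500 + 1,000 individuals with
four archetypes. The pipeline demo (n = 5,000, 60 variants) completes end to
end on one CPU in well under ten minutes.

## What passing tests do and do not show

The generator emulates block LD, haplotype-class epistasis, planted pairwise
interactions, polygenic background, covariate structure and subtype-linked
clinical outcomes. It does not emulate imputation error, genotyping batch
effects, cryptic relatedness, realistic genome-scale variant counts, X
chromosome conventions, ancestry heterogeneity, or linkage between the
clinical model and glycemic control. Passing tests therefore demonstrate
that the statistical machinery recovers what was planted under the stated
architecture — not that the same settings would reproduce any particular
real-cohort estimate. Known limitations: the cross-pair interaction z-test
is a heuristic calibrated here only under the additive null; tree-model
interaction attributions respond to feature correlation and support
constraints, so interaction discovery on LD-correlated panels conflates
epistasis with substitution; and the Youden scale's nearest-rank centile
convention makes thresholds step-wise at small n.
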