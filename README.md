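# t1grs-lab

Genetic risk analysis for type 1 diabetes (T1D) as a reusable, tested
pipeline, exercised end to end on synthetic cohorts with a machine-readable
truth record. It is written for statistical geneticists who want the
analysis machinery behind a nonlinear (tree-ensemble) genetic risk score —
association through fine-mapping, scoring, interaction discovery and
genetic subtyping — in one place, with every step's recovery properties
demonstrated against planted effects.

## What it computes

- **Association & meta-analysis** — per-cohort Firth-penalized logistic
  regression (maximizing `ℓ(β) + ½ log|I(β)|`, finite under complete
  separation), fixed-effects inverse-variance meta-analysis
  (`β = Σwᵢβᵢ/Σwᵢ`, `se = (Σwᵢ)^(-1/2)`), two-round LD clumping with ±500 kb
  locus definition, and stepwise conditional signal discovery with optional
  preconditioning covariates (e.g. 70 allele dosages + 20 interaction
  indicators).
- **Fine-mapping** — Wakefield approximate Bayes factors
  `BF = √(V/(V+W))·exp(z²W/(2(V+W)))`, PIPs normalized over the r² > 0.1
  linkage set, greedy 95% credible sets, and a coverage-calibration harness.
- **Risk model** — gradient-boosted trees (254 trees, depth 5, learning rate
  0.12) scored out-of-fold under stratified 10-fold CV, against an
  L2-logistic baseline (C = 0.001) and a generic additive GRS; AUC/AP,
  paired DeLong tests, per-diplotype-class McNemar error contrasts, and a
  Youden diagnostic scale (J = sensitivity + specificity − 1) over
  case-score centiles.
- **Interpretation** — exact TreeSHAP attributions and pairwise interaction
  tensors on the log-odds scale, a z-score/FDR interaction test against a
  cross-pair background, per-individual complexity scores `C = Σⱼ|φⱼ|`, and
  2-D partial dependence.
- **Subtyping** — PCA (≤175 PCs) of attribution vectors, kNN graph (k=120),
  Leiden clustering (resolution 0.05), UMAP layout (min_dist 0.25),
  validation projection, per-cluster feature statistics, cell-type
  permutation enrichment, onset log-rank tests and complication odds ratios.
- **Synthetic cohorts** — block-LD genotypes via a thresholded Gaussian
  copula, a DR3/DR4/X MHC-analog haplotype system with a 16-fold
  heterozygote risk class, planted epistatic pairs, polygenic background,
  covariates and subtype-linked clinical outcomes, all recorded in a truth
  record sufficient to regenerate the cohort from its seed.

## Worked example

```python
import numpy as np
from t1grs_lab import simulate
from t1grs_lab.assoc import firth_logistic, ivw_meta
from t1grs_lab.finemap import wakefield_bf, credible_set

# two cohorts, one planted common risk variant (log-OR 0.4)
panel = [simulate.VariantSpec(id="v0", chrom="1", pos=100, ref="A", alt="G",
                              maf=0.3, block_id=0)]
per_cohort = []
for seed in (1, 2):
    G = simulate.simulate_genotypes(panel, 8000, ld_rho=0.0, seed=seed)
    eff = simulate.EffectSpec(additive={"v0": 0.4}, intercept=-0.85)
    y = simulate.simulate_phenotypes(G, panel, eff, seed=seed)
    per_cohort.append(firth_logistic(y, G[:, 0], variant_id="v0"))
m = ivw_meta(per_cohort)
print(f"meta: beta={m.beta:.4f} se={m.se:.4f} p={m.p:.2e}")

bf = wakefield_bf(m.beta, m.se, W=0.04)
cs = credible_set(["v0"], np.atleast_1d(bf))
print(f"BF={float(bf):.2e} PIP={cs.table['pip'].iloc[0]:.2f}")
```

prints

```
meta: beta=0.4152 se=0.0254 p=4.32e-60
BF=1.70e+56 PIP=1.00
```

— the meta-analyzed Firth estimate recovers the planted log-OR 0.4 within
one standard error, and the Wakefield Bayes factor (evidence for
association) is astronomically large for so strong a signal, giving the
variant the full posterior mass of its one-variant set.

At study scale, `analysis/04_risk_model.py` on the default simulated
discovery cohort (n = 6,000, 200 variants) prints out-of-fold
discrimination for the boosted model against the logistic baseline and the
Youden scale of the score, e.g. best J 0.567 at a score threshold of 0.386
(75% sensitivity, 82% specificity), and `analysis/03_finemap.py` reports the
credible-set calibration — 97.2% of 400 matched-prior regions covered the
planted causal variant.

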