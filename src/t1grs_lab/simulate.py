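"""Synthetic cohort generator.

Emulates the genetic architecture assumed by the analysis: block-LD dosage
genotypes over a ~200-variant panel, an MHC-analog locus with DR3/DR4/X
haplotype classes and a heterozygote super-risk interaction, planted pairwise
epistasis, an additive polygenic background, covariates (sex, four genotype
PCs, cohort indicator) and binary disease labels from a logistic model, plus
per-subtype age-of-onset and complication outcomes.

LD model: per LD block, haplotype alleles are drawn from an AR(1) Gaussian
copula thresholded at each variant's allele frequency, which gives
controllable pairwise r-squared without a haplotype reference panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from ._seeds import child_seed
from .cohort import (
    COMPLICATIONS,
    MHC_GROUP,
    NON_MHC_GROUP,
    ClinicalSpec,
    CohortData,
    EffectSpec,
    MhcSpec,
    TruthRecord,
    VariantSpec,
    validate_panel,
)


def simulate_genotypes(
    panel: list[VariantSpec],
    n: int,
    ld_rho: float | dict[int, float] = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Draw an ``n x len(panel)`` dosage matrix with within-block LD.

    Each individual is the sum of two independent haplotypes. Within a block,
    latent Gaussians follow an AR(1) process with parameter ``ld_rho`` (scalar
    or per-block dict); an allele is alt when its latent value falls below the
    normal quantile of the variant's MAF, so marginal allele frequencies equal
    the specified MAFs while adjacent-variant correlation grows with rho.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    validate_panel(panel)
    rng = np.random.default_rng(seed)

    def rho_for(block: int) -> float:
        r = ld_rho[block] if isinstance(ld_rho, dict) else ld_rho
        if not (0.0 <= r < 1.0) and not np.isclose(r, 1.0, atol=1e-9):
            raise ValueError(f"ld_rho for block {block} must be in [0, 1)")
        return min(float(r), 1.0 - 1e-12)

    p = len(panel)
    dosage = np.zeros((n, p), dtype=np.int8)
    blocks: dict[int, list[int]] = {}
    for j, v in enumerate(panel):
        blocks.setdefault(v.block_id, []).append(j)

    for block_id, cols in blocks.items():
        rho = rho_for(block_id)
        m = len(cols)
        thresh = stats.norm.ppf([panel[j].maf for j in cols])
        for _hap in range(2):
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            for k in range(1, m):
                z[:, k] = rho * z[:, k - 1] + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
            alleles = (z < thresh[None, :]).astype(np.int8)
            dosage[:, cols] += alleles
    return dosage


def assign_mhc(
    dosage: np.ndarray,
    panel: list[VariantSpec],
    mhc: MhcSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw MHC-analog diplotypes and overwrite tag-variant dosages.

    Two haplotypes per individual are drawn independently from the DR3/DR4/X
    frequencies (Hardy-Weinberg). Tag-variant dosage is set to the copy count
    of the tagged haplotype. Returns ``(dosage, diplotype_class)`` where the
    class is one of ``DIPLOTYPE_CLASSES``.
    """
    rng = np.random.default_rng(seed)
    n = dosage.shape[0]
    haps = np.array(["DR3", "DR4", "X"], dtype=object)
    freqs = np.array([mhc.frequencies[h] for h in haps])
    draws = rng.choice(3, size=(n, 2), p=freqs)
    h1, h2 = haps[draws[:, 0]], haps[draws[:, 1]]

    copies = {h: (h1 == h).astype(np.int8) + (h2 == h).astype(np.int8) for h in ("DR3", "DR4")}

    id_to_col = {v.id: j for j, v in enumerate(panel)}
    out = dosage.copy()
    for hap, tags in mhc.tag_variants.items():
        if hap == "X":
            continue
        for tag in tags:
            if tag not in id_to_col:
                raise KeyError(f"tag variant {tag} not in panel")
            out[:, id_to_col[tag]] = copies[hap]

    cls = np.full(n, "none", dtype=object)
    n_risk = copies["DR3"] + copies["DR4"]
    cls[n_risk == 1] = "one DR3 or DR4"
    cls[(copies["DR3"] == 2) | (copies["DR4"] == 2)] = "DR3/DR3 or DR4/DR4"
    cls[(copies["DR3"] == 1) & (copies["DR4"] == 1)] = "DR3/DR4"
    return out, cls


def _logit_risk(
    dosage: np.ndarray,
    panel: list[VariantSpec],
    effects: EffectSpec,
    covariates: pd.DataFrame | None,
    diplotype_class: np.ndarray | None,
    mhc: MhcSpec | None,
) -> np.ndarray:
    """Linear predictor of the planted logistic disease model."""
    id_to_col = {v.id: j for j, v in enumerate(panel)}
    missing = effects.referenced_ids() - set(id_to_col)
    if missing:
        raise KeyError(f"effects reference unknown variants: {sorted(missing)}")

    eta = np.full(dosage.shape[0], effects.intercept, dtype=float)
    for vid, b in effects.additive.items():
        eta += b * dosage[:, id_to_col[vid]]
    for a, b, w in effects.interactions:
        da, db = dosage[:, id_to_col[a]], dosage[:, id_to_col[b]]
        if effects.interaction_encoding == "carrier":
            term = ((da > 0) & (db > 0)).astype(float)
        else:
            term = da.astype(float) * db.astype(float)
        eta += w * term
    if covariates is not None:
        for name, b in effects.covariate_betas.items():
            if name not in covariates.columns:
                raise KeyError(f"unknown covariate: {name}")
            eta += b * covariates[name].to_numpy(dtype=float)
    if mhc is not None and diplotype_class is not None and mhc.het_bonus:
        # per-copy haplotype effects enter through their tag dosages in
        # effects.additive; only the heterozygote bonus is class-specific
        eta += mhc.het_bonus * (diplotype_class == "DR3/DR4").astype(float)
    return eta


def simulate_phenotypes(
    dosage: np.ndarray,
    panel: list[VariantSpec],
    effects: EffectSpec,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    diplotype_class: np.ndarray | None = None,
    mhc: MhcSpec | None = None,
) -> np.ndarray:
    """Draw binary disease labels from the planted logistic model.

    ``P(case | x) = expit(intercept + additive + interactions + covariates)``,
    where MHC haplotype per-copy effects enter through their tag-variant
    dosages in ``effects.additive`` and the DR3/DR4 heterozygote bonus enters
    iff the individual's diplotype class is DR3/DR4.
    """
    rng = np.random.default_rng(seed)
    eta = _logit_risk(dosage, panel, effects, covariates, diplotype_class, mhc)
    return (rng.random(dosage.shape[0]) < expit(eta)).astype(np.int8)


def simulate_clinical(
    labels: np.ndarray,
    subtypes: np.ndarray,
    spec: ClinicalSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw onset ages and complication indicators for cases.

    Onset is truncated-normal (at 0) with per-subtype location/scale;
    complications are Bernoulli with the subtype's odds multiplier applied to
    the baseline probability on the odds scale. Controls get NaN onset and
    zero complication flags.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    case = labels == 1
    if subtypes is None or len(subtypes) != n:
        raise ValueError("subtypes must be provided per individual")
    for s in np.unique(np.asarray(subtypes, dtype=object)[case]):
        if s not in spec.onset:
            raise KeyError(f"no onset distribution for subtype {s!r}")

    onset = np.full(n, np.nan)
    flags = {c: np.zeros(n, dtype=np.int8) for c in COMPLICATIONS}
    for s, (loc, scale) in spec.onset.items():
        mask = case & (np.asarray(subtypes, dtype=object) == s)
        k = int(mask.sum())
        if k == 0:
            continue
        a = (0.0 - loc) / scale
        onset[mask] = stats.truncnorm.rvs(
            a, np.inf, loc=loc, scale=scale, size=k, random_state=rng
        )
        for comp in COMPLICATIONS:
            base = spec.complication_base.get(comp)
            if base is None:
                continue
            mult = spec.complication_odds.get(s, {}).get(comp, 1.0)
            p = expit(logit(base) + np.log(mult))
            flags[comp][mask] = rng.random(k) < p
    out = pd.DataFrame({"onset_age": onset, **flags})
    return out


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

#: Haplotype frequencies of the MHC analog; roughly the European-ancestry
#: carriage of the high-risk DR3 and DR4 haplotype classes.
DEFAULT_MHC = MhcSpec(
    frequencies={"DR3": 0.15, "DR4": 0.15, "X": 0.70},
    tag_variants={"DR3": ["mhc_DR3_tag"], "DR4": ["mhc_DR4_tag"]},
    log_or={"DR3": np.log(3.0), "DR4": np.log(3.0)},
    het_bonus=float(np.log(16.0) - 2 * np.log(3.0)),  # het class sits at OR 16
)

#: Per-subtype clinical model. The planted pancreas-like subtype S3 has the
#: latest onset but elevated complication odds (CVD 1.46-fold, nephropathy
#: 1.29-fold, neuropathy 1.35-fold); MHC-driven subtypes onset earliest.
DEFAULT_CLINICAL = ClinicalSpec(
    onset={
        "S0": (12.0, 6.0),
        "S1": (14.0, 7.0),
        "S2": (17.0, 8.0),
        "S3": (22.0, 9.0),
    },
    complication_base={"nephropathy": 0.15, "neuropathy": 0.15, "cvd": 0.12, "retinopathy": 0.20},
    complication_odds={
        "S3": {"nephropathy": 1.29, "neuropathy": 1.35, "cvd": 1.46}
    },
)


def make_panel(
    n_mhc: int = 30,
    n_nonmhc: int = 170,
    block_size: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    annotations: tuple[str, ...] = ("T_cell", "B_cell", "pancreatic_islet", "NK_cell"),
) -> list[VariantSpec]:
    """Build a default ~200-variant panel: an MHC-analog block plus LD blocks
    of genome-wide background variants with MAFs drawn uniformly and synthetic
    cell-type annotations cycling over ``annotations``."""
    rng = np.random.default_rng(seed)
    panel: list[VariantSpec] = []
    pos = 30_000_000
    # MHC analog on chr6: two haplotype tags plus surrounding variants
    for i in range(n_mhc):
        pos += rng.integers(5_000, 50_000)
        if i == 0:
            vid = "mhc_DR3_tag"
        elif i == 1:
            vid = "mhc_DR4_tag"
        else:
            vid = f"mhc_v{i}"
        panel.append(
            VariantSpec(
                id=vid, chrom="6", pos=int(pos), ref="A", alt="G",
                maf=float(rng.uniform(*maf_range)) if i >= 2 else 0.15,
                block_id=i // block_size, group=MHC_GROUP,
                annotation=annotations[i % len(annotations)],
            )
        )
    n_mhc_blocks = (n_mhc + block_size - 1) // block_size
    pos = 1_000_000
    for i in range(n_nonmhc):
        pos += rng.integers(100_000, 900_000)
        panel.append(
            VariantSpec(
                id=f"gw_v{i}", chrom="1", pos=int(pos), ref="C", alt="T",
                maf=float(rng.uniform(*maf_range)),
                block_id=n_mhc_blocks + i // block_size, group=NON_MHC_GROUP,
                annotation=annotations[i % len(annotations)],
            )
        )
    return panel


def default_effects(
    panel: list[VariantSpec],
    seed: int = 0,
    prevalence: float = 0.34,
    polygenic_sd: float = 0.18,
    mhc_sd: float = 0.6,
    n_interactions: int = 2,
    interaction_log_or: float = 0.7,
) -> EffectSpec:
    """Planted architecture: MHC tag effects, a polygenic background over all
    non-MHC variants, and ``n_interactions`` planted epistatic pairs (the
    first MHC x genome-wide, the rest genome-wide x genome-wide).

    The intercept is centered analytically (subtracting the expected genetic
    contribution under independence) so that mean disease probability sits
    near ``prevalence`` — by default the case-enriched level typical of
    combined case-control study panels, ~1 case : 2 controls.
    """
    rng = np.random.default_rng(seed)
    additive = {"mhc_DR3_tag": float(np.log(3.0)), "mhc_DR4_tag": float(np.log(3.0))}
    # independent MHC signals beyond the two haplotype tags, echoing the many
    # conditional class I/II association signals of the region
    for v in panel:
        if v.group == MHC_GROUP and v.id not in additive:
            additive[v.id] = float(rng.normal(0.0, mhc_sd))
    nonmhc = [v.id for v in panel if v.group == NON_MHC_GROUP]
    for vid in nonmhc:
        additive[vid] = float(rng.normal(0.0, polygenic_sd))
    interactions: list[tuple[str, str, float]] = []
    common = [v.id for v in panel if v.group == NON_MHC_GROUP and v.maf >= 0.2]
    if n_interactions >= 1 and common:
        interactions.append(("mhc_DR4_tag", common[0], interaction_log_or))
    for k in range(1, n_interactions):
        if 2 * k + 1 < len(common):
            interactions.append((common[2 * k], common[2 * k + 1], interaction_log_or))
    maf = {v.id: v.maf for v in panel}
    offset = sum(b * 2 * maf[vid] for vid, b in additive.items())
    offset += sum(w * 4 * maf[a] * maf[b] for a, b, w in interactions)
    # logistic-normal mean correction: with Var(eta) = s2, the population
    # prevalence is approximately expit(mu / sqrt(1 + 0.346 s2)), so the
    # target logit is inflated accordingly before subtracting the offset
    s2 = sum(b * b * 2 * maf[vid] * (1 - maf[vid]) for vid, b in additive.items())
    mu = float(logit(prevalence)) * np.sqrt(1 + 0.346 * s2)
    return EffectSpec(
        additive=additive,
        interactions=interactions,
        intercept=float(mu - offset),
        covariate_betas={"sex": 0.1, "PC1": 0.05},
    )


def interaction_discovery_effects(
    panel: list[VariantSpec],
    seed: int = 0,
    interaction_log_or: float = 0.7,
    prevalence: float = 0.34,
) -> EffectSpec:
    """Architecture for the interaction-discovery experiment: one planted
    multiplicative MHC x non-MHC pair between common variants (both MAFs
    >= 0.2, so carrier classes are well populated), on top of moderate
    additive effects."""
    base = default_effects(
        panel, seed=seed, prevalence=prevalence, polygenic_sd=0.25,
        mhc_sd=0.35, n_interactions=0,
    )
    mhc_common = [v.id for v in panel
                  if v.group == MHC_GROUP and v.maf >= 0.2 and "tag" not in v.id]
    if not mhc_common:
        nontag = [v for v in panel if v.group == MHC_GROUP and "tag" not in v.id]
        mhc_common = [max(nontag, key=lambda v: v.maf).id] if nontag else []
    gw_common = [v.id for v in panel if v.group == NON_MHC_GROUP and v.maf >= 0.2]
    if not mhc_common or not gw_common:
        raise ValueError("panel lacks common variants for the planted pair")
    pair = (mhc_common[0], gw_common[0], float(interaction_log_or))
    maf = {v.id: v.maf for v in panel}
    pair_offset = interaction_log_or * 4 * maf[pair[0]] * maf[pair[1]]
    return EffectSpec(
        additive=base.additive,
        interactions=[pair],
        intercept=base.intercept - pair_offset,
        covariate_betas=base.covariate_betas,
    )


def additive_null_effects(
    panel: list[VariantSpec],
    seed: int = 0,
    effect_sd: float = 0.25,
    prevalence: float = 0.34,
) -> EffectSpec:
    """Strictly additive architecture for null calibration of interaction
    discovery: every variant (tags included) gets a moderate additive log-OR,
    no epistatic pairs and no heterozygote bonus. Pair with ``mhc=None`` and
    ``ld_rho=0`` so that neither the haplotype-class constraint (DR3 + DR4
    copies cannot exceed two) nor correlated features induce model
    interactions that are not epistasis."""
    base = default_effects(
        panel, seed=seed, prevalence=prevalence, polygenic_sd=effect_sd,
        mhc_sd=effect_sd, n_interactions=0,
    )
    additive = dict(base.additive)
    rng = np.random.default_rng(seed + 1)
    for tag in ("mhc_DR3_tag", "mhc_DR4_tag"):
        if tag in additive:
            additive[tag] = float(abs(rng.normal(0.0, effect_sd)))
    maf = {v.id: v.maf for v in panel}
    offset = sum(b * 2 * maf[vid] for vid, b in additive.items())
    s2 = sum(b * b * 2 * maf[vid] * (1 - maf[vid]) for vid, b in additive.items())
    mu = float(logit(prevalence)) * np.sqrt(1 + 0.346 * s2)
    return EffectSpec(
        additive=additive, interactions=[], intercept=float(mu - offset),
        covariate_betas=base.covariate_betas,
    )


def simulate_covariates(n: int, n_cohorts: int = 2, seed: int = 0) -> pd.DataFrame:
    """Sex (0/1), four genotype PCs (standard normal with small per-cohort
    offsets on PC1/PC2 as a population-structure stand-in) and a cohort id."""
    rng = np.random.default_rng(seed)
    cohort = rng.integers(0, n_cohorts, size=n)
    pcs = rng.standard_normal((n, 4))
    pcs[:, 0] += 0.3 * cohort
    pcs[:, 1] -= 0.2 * cohort
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "PC1": pcs[:, 0],
            "PC2": pcs[:, 1],
            "PC3": pcs[:, 2],
            "PC4": pcs[:, 3],
            "cohort": cohort,
        }
    )


def simulate_cohort(
    n: int = 5000,
    panel: list[VariantSpec] | None = None,
    effects: EffectSpec | None = None,
    mhc: MhcSpec | None = DEFAULT_MHC,
    clinical: ClinicalSpec | None = DEFAULT_CLINICAL,
    ld_rho: float = 0.7,
    n_cohorts: int = 2,
    n_subtypes: int = 4,
    seed: int = 0,
) -> CohortData:
    """End-to-end cohort draw under the default study conditions.

    Every stochastic step uses a child seed derived from ``(seed, step-name)``
    so stages are independently reproducible. Planted case subtypes are drawn
    uniformly and recorded in the TruthRecord; clinical outcomes follow the
    subtype model.
    """
    if panel is None:
        panel = make_panel(seed=child_seed(seed, "panel"))
    if effects is None:
        effects = default_effects(panel, seed=child_seed(seed, "effects"))

    dosage = simulate_genotypes(panel, n, ld_rho=ld_rho, seed=child_seed(seed, "genotypes"))
    if mhc is not None:
        dosage, dip = assign_mhc(dosage, panel, mhc, seed=child_seed(seed, "mhc"))
    else:
        dip = np.full(n, "none", dtype=object)
    covars = simulate_covariates(n, n_cohorts=n_cohorts, seed=child_seed(seed, "covariates"))
    labels = simulate_phenotypes(
        dosage, panel, effects, seed=child_seed(seed, "phenotypes"),
        covariates=covars, diplotype_class=dip, mhc=mhc,
    )
    rng = np.random.default_rng(child_seed(seed, "subtypes"))
    subtype_names = [f"S{i}" for i in range(n_subtypes)]
    subtypes = np.asarray(rng.choice(subtype_names, size=n), dtype=object)

    samples = covars.copy()
    samples.insert(0, "sample_id", [f"ind{i:06d}" for i in range(n)])
    samples["label"] = labels
    samples["diplotype_class"] = dip
    if clinical is not None:
        clin = simulate_clinical(labels, subtypes, clinical, seed=child_seed(seed, "clinical"))
        for c in clin.columns:
            samples[c] = clin[c].to_numpy()
    truth = TruthRecord(
        seed=seed, panel=panel, mhc=mhc, effects=effects, clinical=clinical,
        subtype=subtypes,
    )
    return CohortData(dosage=dosage, variant_ids=[v.id for v in panel], samples=samples, truth=truth)


def simulate_shap_archetypes(
    n: int,
    n_features: int = 40,
    k: int = 4,
    separation: float = 3.0,
    noise_sd: float = 0.3,
    features_per_archetype: int = 4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate an attribution matrix with ``k`` planted archetypes.

    Each archetype has a disjoint set of dominant features whose mean
    attribution is ``separation * noise_sd`` above background; all entries
    carry Gaussian noise. Returns ``(matrix, archetype_labels)``. This is the
    planted-truth input for subtype-recovery experiments: it emulates the
    structure of per-individual SHAP vectors without fitting a model.
    """
    if k * features_per_archetype > n_features:
        raise ValueError("not enough features for the requested archetypes")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=n)
    mat = rng.normal(0.0, noise_sd, size=(n, n_features))
    for a in range(k):
        cols = slice(a * features_per_archetype, (a + 1) * features_per_archetype)
        mat[labels == a, cols] += separation * noise_sd
    return mat, labels
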