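"""Domain types for synthetic case-control cohorts.

The central container is :class:`CohortData`: a dosage matrix over a variant
panel, per-sample covariates and outcomes, and a :class:`TruthRecord` holding
every planted effect so downstream recovery can be checked against ground
truth. Specs are plain dataclasses; all randomness lives in
:mod:`t1grs_lab.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

MHC_GROUP = "MHC"
NON_MHC_GROUP = "NON_MHC"

#: Diplotype classes, ordered from highest-risk to baseline.
DIPLOTYPE_CLASSES = ("DR3/DR4", "DR3/DR3 or DR4/DR4", "one DR3 or DR4", "none")

COMPLICATIONS = ("nephropathy", "neuropathy", "cvd", "retinopathy")


@dataclass(frozen=True)
class VariantSpec:
    """One biallelic variant in the panel.

    ``maf`` is the alternate-allele frequency in (0, 0.5]; ``block_id``
    labels the LD block the variant belongs to; ``group`` separates the
    MHC-analog region from genome-wide background; ``annotation`` is an
    optional cell-type label standing in for regulatory annotation.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    block_id: int
    group: Literal["MHC", "NON_MHC"] = NON_MHC_GROUP
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf for {self.id} must be in (0, 0.5], got {self.maf}")
        if self.pos < 1:
            raise ValueError(f"pos for {self.id} must be 1-based positive")


def validate_panel(panel: list[VariantSpec]) -> None:
    """Check panel-level invariants: unique ids, increasing positions per chrom."""
    seen: set[str] = set()
    for v in panel:
        if v.id in seen:
            raise ValueError(f"duplicate variant id: {v.id}")
        seen.add(v.id)
    by_chrom: dict[str, int] = {}
    for v in panel:
        if v.chrom in by_chrom and v.pos <= by_chrom[v.chrom]:
            raise ValueError(
                f"positions must be strictly increasing within {v.chrom} (at {v.id})"
            )
        by_chrom[v.chrom] = v.pos


@dataclass(frozen=True)
class MhcSpec:
    """MHC-analog haplotype system.

    Three haplotype classes (DR3, DR4, X) with population frequencies; each
    risk haplotype is tagged by one or more panel variants whose dosage equals
    the haplotype copy count. ``log_or`` gives the per-copy effect of each
    haplotype; ``het_bonus`` is the extra log-odds applied only to DR3/DR4
    heterozygotes, encoding the super-additive risk of that genotype.
    """

    frequencies: dict[str, float]
    tag_variants: dict[str, list[str]]
    log_or: dict[str, float]
    het_bonus: float = 0.0

    def __post_init__(self) -> None:
        if set(self.frequencies) != {"DR3", "DR4", "X"}:
            raise ValueError("haplotype labels must be exactly {DR3, DR4, X}")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1, got {total}")
        for hap in ("DR3", "DR4"):
            if not self.tag_variants.get(hap):
                raise ValueError(f"haplotype {hap} needs at least one tag variant")


@dataclass(frozen=True)
class EffectSpec:
    """Planted genetic architecture on the log-odds scale.

    ``additive`` maps variant id -> per-alt-allele log-OR; ``interactions``
    is a list of (id_a, id_b, log-OR) pairwise epistatic terms;
    ``interaction_encoding`` selects how a pair contributes to the logit:
    ``dosage_product`` (multiplicative on log-odds, the default) or
    ``carrier`` (indicator that both members carry >=1 alt copy).
    """

    additive: dict[str, float] = field(default_factory=dict)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    intercept: float = 0.0
    covariate_betas: dict[str, float] = field(default_factory=dict)
    interaction_encoding: Literal["dosage_product", "carrier"] = "dosage_product"

    def referenced_ids(self) -> set[str]:
        ids = set(self.additive)
        for a, b, _ in self.interactions:
            ids.update((a, b))
        return ids


@dataclass(frozen=True)
class ClinicalSpec:
    """Per-subtype clinical outcome model.

    ``onset``: subtype -> (location, scale) in years for a truncated-normal
    age of onset (truncated at 0). ``complication_base``: baseline probability
    per complication. ``complication_odds``: subtype -> complication -> odds
    multiplier applied on top of the baseline.
    """

    onset: dict[str, tuple[float, float]]
    complication_base: dict[str, float]
    complication_odds: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.complication_base.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"baseline probability for {name} must be in (0,1)")


@dataclass
class TruthRecord:
    """Everything needed to regenerate the cohort and audit recovery."""

    seed: int
    panel: list[VariantSpec]
    mhc: MhcSpec | None
    effects: EffectSpec
    clinical: ClinicalSpec | None
    subtype: np.ndarray | None = None  # planted subtype label per individual ("" = n/a)

    def to_jsonable(self) -> dict:
        out = {
            "seed": self.seed,
            "panel": [asdict(v) for v in self.panel],
            "mhc": asdict(self.mhc) if self.mhc is not None else None,
            "effects": {
                "additive": self.effects.additive,
                "interactions": [list(t) for t in self.effects.interactions],
                "intercept": self.effects.intercept,
                "covariate_betas": self.effects.covariate_betas,
                "interaction_encoding": self.effects.interaction_encoding,
            },
            "clinical": asdict(self.clinical) if self.clinical is not None else None,
            "subtype": None if self.subtype is None else [str(s) for s in self.subtype],
        }
        return out

    @classmethod
    def from_jsonable(cls, d: dict) -> "TruthRecord":
        panel = [VariantSpec(**v) for v in d["panel"]]
        mhc = None
        if d.get("mhc") is not None:
            m = dict(d["mhc"])
            mhc = MhcSpec(
                frequencies=m["frequencies"],
                tag_variants=m["tag_variants"],
                log_or=m["log_or"],
                het_bonus=m["het_bonus"],
            )
        e = d["effects"]
        effects = EffectSpec(
            additive={k: float(v) for k, v in e["additive"].items()},
            interactions=[(a, b, float(w)) for a, b, w in e["interactions"]],
            intercept=float(e["intercept"]),
            covariate_betas={k: float(v) for k, v in e["covariate_betas"].items()},
            interaction_encoding=e["interaction_encoding"],
        )
        clinical = None
        if d.get("clinical") is not None:
            c = d["clinical"]
            clinical = ClinicalSpec(
                onset={k: tuple(v) for k, v in c["onset"].items()},
                complication_base=c["complication_base"],
                complication_odds=c["complication_odds"],
            )
        subtype = None if d.get("subtype") is None else np.asarray(d["subtype"], dtype=object)
        return cls(
            seed=int(d["seed"]), panel=panel, mhc=mhc, effects=effects,
            clinical=clinical, subtype=subtype,
        )


@dataclass
class CohortData:
    """A simulated case-control cohort.

    ``dosage`` is individuals x variants with values {0,1,2} (int8);
    ``samples`` holds sex, PC1-4, cohort id, label, diplotype class, onset
    age (NaN for controls / censored fields) and complication indicators.
    """

    dosage: np.ndarray
    variant_ids: list[str]
    samples: pd.DataFrame
    truth: TruthRecord

    def __post_init__(self) -> None:
        n, p = self.dosage.shape
        if n == 0 or p == 0:
            raise ValueError("empty cohort")
        if len(self.variant_ids) != p:
            raise ValueError("variant_ids length mismatch")
        if len(self.samples) != n:
            raise ValueError("samples table length mismatch")

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.samples["label"].to_numpy(dtype=int)

    @property
    def diplotype_class(self) -> np.ndarray:
        return self.samples["diplotype_class"].to_numpy(dtype=object)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id: {variant_id}") from None
        return self.dosage[:, j]

    def variant_groups(self) -> dict[str, str]:
        return {v.id: v.group for v in self.truth.panel}
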