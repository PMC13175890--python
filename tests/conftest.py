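"""Shared fixtures: small planted-architecture cohorts and trained bundles.

Session scope keeps the expensive pieces (cohort simulation, cross-validated
ensemble training) to one instance reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from t1grs_lab import simulate
from t1grs_lab.cohort import VariantSpec
from t1grs_lab.riskmodel import assemble_features, train_gbdt_cv, train_logreg_cv
from t1grs_lab.simulate import make_panel


def small_panel(n_mhc: int = 8, n_nonmhc: int = 16, seed: int = 7) -> list[VariantSpec]:
    return make_panel(n_mhc=n_mhc, n_nonmhc=n_nonmhc, block_size=4, seed=seed)


def epistatic_cohort(n: int = 6000, seed: int = 11, interaction_log_or: float = 1.2):
    """Cohort with a strong MHC architecture and planted epistatic pairs."""
    panel = small_panel()
    effects = simulate.default_effects(
        panel, seed=seed, polygenic_sd=0.25, n_interactions=2,
        interaction_log_or=interaction_log_or,
    )
    return simulate.simulate_cohort(
        n=n, panel=panel, effects=effects, seed=seed, n_subtypes=4
    )


def additive_cohort(n: int = 10_000, seed: int = 13, effect_sd: float = 0.6):
    """Strictly additive generator: no planted interactions, no haplotype
    classes, variants in linkage equilibrium — the model-facing panel
    emulates LD-clumped lead variants, so neither correlated-feature
    substitution nor the diplotype support constraint masquerades as
    epistasis in the null condition."""
    panel = small_panel()
    effects = simulate.additive_null_effects(panel, seed=seed, effect_sd=effect_sd)
    return simulate.simulate_cohort(
        n=n, panel=panel, effects=effects, mhc=None, seed=seed, n_subtypes=4,
        ld_rho=0.0,
    )


@pytest.fixture(scope="session")
def epi_cohort():
    return epistatic_cohort()


@pytest.fixture(scope="session")
def add_cohort():
    return additive_cohort()


@pytest.fixture(scope="session")
def epi_features(epi_cohort):
    return assemble_features(epi_cohort, submodel="ALL")


@pytest.fixture(scope="session")
def epi_gbdt(epi_cohort, epi_features):
    return train_gbdt_cv(epi_features, epi_cohort.labels, k=5, seed=3)


@pytest.fixture(scope="session")
def epi_logreg(epi_cohort, epi_features):
    return train_logreg_cv(epi_features, epi_cohort.labels, k=5, seed=3)


@pytest.fixture(scope="session")
def add_features(add_cohort):
    return assemble_features(add_cohort, submodel="ALL")


@pytest.fixture(scope="session")
def add_gbdt(add_cohort, add_features):
    return train_gbdt_cv(add_features, add_cohort.labels, k=5, seed=3)
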