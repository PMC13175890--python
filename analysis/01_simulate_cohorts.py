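"""Simulate the discovery and validation cohorts under the default study
conditions (200-variant panel with an MHC-analog locus, planted epistasis,
polygenic background, covariates, clinical outcomes) and serialize them.

Outputs: results/cohorts/discovery/, results/cohorts/validation/
"""

from pathlib import Path

from t1grs_lab import io, simulate

OUT = Path("results/cohorts")
SEED = 20240901

if __name__ == "__main__":
    discovery = simulate.simulate_cohort(n=6000, seed=SEED)
    validation = simulate.simulate_cohort(
        n=3000, panel=discovery.truth.panel, effects=discovery.truth.effects,
        seed=SEED + 1,
    )
    io.write_cohort(discovery, OUT / "discovery")
    io.write_cohort(validation, OUT / "validation")
    for name, c in (("discovery", discovery), ("validation", validation)):
        print(
            f"{name}: n={c.n}, variants={len(c.variant_ids)}, "
            f"prevalence={c.labels.mean():.3f}, "
            f"DR3/DR4 heterozygotes={(c.diplotype_class == 'DR3/DR4').mean():.3%}"
        )
    print(f"written to {OUT}/")
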