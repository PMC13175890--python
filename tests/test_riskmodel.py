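"""Risk model: feature assembly, out-of-fold discipline, baseline ordering,
and the evaluation statistics against hand-computed oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from t1grs_lab.riskmodel import (
    additive_grs,
    assemble_features,
    auc,
    average_precision,
    delong_test,
    mcnemar_pair,
    mcnemar_strata,
    train_gbdt_cv,
    train_logreg_cv,
    youden_index,
    youden_scale,
)


class TestAssembleFeatures:
    def test_all_is_union_of_submodels(self, epi_cohort):
        all_f = assemble_features(epi_cohort, submodel="ALL")
        mhc = assemble_features(epi_cohort, submodel="MHC_ONLY")
        non = assemble_features(epi_cohort, submodel="NON_MHC")
        assert set(all_f.feature_names) == set(mhc.feature_names) | set(non.feature_names)
        assert not set(mhc.feature_names) & set(non.feature_names)

    def test_covariates_add_expected_columns(self, epi_cohort):
        base = assemble_features(epi_cohort, submodel="ALL")
        cov = assemble_features(epi_cohort, submodel="ALL", with_covars=True)
        extra = set(cov.feature_names) - set(base.feature_names)
        n_cohorts = epi_cohort.samples["cohort"].nunique()
        assert extra == {"sex", "PC1", "PC2", "PC3", "PC4"} | {
            f"cohort_{c}" for c in sorted(epi_cohort.samples["cohort"].unique())
        }
        assert all(cov.groups[f] == "COVAR" for f in extra)
        assert len(extra) == 5 + n_cohorts

    def test_negative_beta_flips_dosage(self, epi_cohort):
        vid = epi_cohort.variant_ids[5]
        flipped = assemble_features(epi_cohort, betas={vid: -0.5})
        plain = assemble_features(epi_cohort)
        assert flipped.flipped[vid]
        assert np.allclose(
            flipped.X[vid].to_numpy(), 2.0 - plain.X[vid].to_numpy()
        )


class TestCrossValidation:
    def test_every_individual_scored_once(self, epi_gbdt):
        assert not np.any(np.isnan(epi_gbdt.oof_scores))
        assert len(np.unique(epi_gbdt.fold_assignment)) == 5

    def test_folds_partition_cohort(self, epi_gbdt, epi_cohort):
        counts = np.bincount(epi_gbdt.fold_assignment)
        assert counts.sum() == epi_cohort.n
        assert counts.max() - counts.min() <= 1

    def test_rerun_same_seed_identical(self, epi_cohort, epi_features, epi_gbdt):
        again = train_gbdt_cv(epi_features, epi_cohort.labels, k=5, seed=3)
        assert np.array_equal(again.oof_scores, epi_gbdt.oof_scores)

    def test_planted_architecture_gives_strong_auc(self, epi_gbdt, epi_cohort):
        # MHC OR ~16 heterozygote class plus polygenic background is a
        # strong signal; out-of-fold AUC should be well above chance
        assert auc(epi_gbdt.oof_scores, epi_cohort.labels) > 0.75

    def test_gbdt_beats_logreg_under_epistasis(self, epi_gbdt, epi_logreg, epi_cohort):
        y = epi_cohort.labels
        assert auc(epi_gbdt.oof_scores, y) > auc(epi_logreg.oof_scores, y)

    def test_stronger_regularization_shrinks_coefficients(self, epi_cohort, epi_features):
        weak = train_logreg_cv(epi_features, epi_cohort.labels, l2_c=1.0, k=5, seed=3)
        strong = train_logreg_cv(epi_features, epi_cohort.labels, l2_c=0.001, k=5, seed=3)
        for mw, ms in zip(weak.models, strong.models):
            assert np.linalg.norm(ms.coef_) <= np.linalg.norm(mw.coef_) + 1e-9


class TestAdditiveGrs:
    def test_zero_weights_constant(self, epi_cohort):
        s = additive_grs(epi_cohort, {v: 0.0 for v in epi_cohort.variant_ids})
        assert np.ptp(s) == 0

    def test_single_unit_weight_equals_dosage(self, epi_cohort):
        vid = epi_cohort.variant_ids[0]
        s = additive_grs(epi_cohort, {vid: 1.0})
        assert np.array_equal(s, epi_cohort.dosage_of(vid).astype(float))

    def test_diplotype_term_only_affects_that_class(self, epi_cohort):
        vid = epi_cohort.variant_ids[0]
        base = additive_grs(epi_cohort, {vid: 1.0})
        with_term = additive_grs(epi_cohort, {vid: 1.0}, [("DR3/DR4", 2.0)])
        het = epi_cohort.diplotype_class == "DR3/DR4"
        assert np.allclose(with_term[het] - base[het], 2.0)
        assert np.allclose(with_term[~het], base[~het])


class TestAucOracles:
    def test_perfect_separation(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        s = np.r_[np.zeros(5), np.ones(5)]
        assert auc(s, y) == 1.0

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(3)
        s = rng.choice([0.1, 0.4, 0.4, 0.8], size=10)
        y = rng.integers(0, 2, size=10)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pos, neg = s[y == 1], s[y == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
        assert auc(s, y) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(4)
        aucs = [
            auc(rng.normal(size=400), rng.integers(0, 2, size=400)) for _ in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_average_precision_bounds(self):
        rng = np.random.default_rng(5)
        ap = average_precision(rng.normal(size=100), rng.integers(0, 2, size=100))
        assert 0.0 <= ap <= 1.0


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        a, b, p = delong_test(s, s, y)
        assert a == b and p == 1.0

    def test_agrees_with_paired_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 200
        signal = rng.normal(size=n)
        y = (signal + rng.normal(size=n) > 0).astype(int)
        sa = signal + rng.normal(scale=0.8, size=n)
        sb = signal + rng.normal(scale=1.6, size=n)
        _, _, p_delong = delong_test(sa, sb, y)
        # paired bootstrap of the AUC difference
        diffs = []
        for _ in range(400):
            idx = rng.integers(0, n, size=n)
            if y[idx].min() == y[idx].max():
                continue
            diffs.append(auc(sa[idx], y[idx]) - auc(sb[idx], y[idx]))
        diffs = np.asarray(diffs)
        z = diffs.mean() / diffs.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        assert p_delong / 2 <= max(p_boot, 1e-6) * 2 and p_boot / 2 <= p_delong * 2

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(8)
        n = 400
        signal = rng.normal(size=n)
        y = (signal > 0).astype(int)
        good = signal + rng.normal(scale=0.3, size=n)
        bad = rng.normal(size=n)
        _, _, p = delong_test(good, bad, y)
        assert p < 1e-6


class TestMcnemar:
    def test_identical_predictions(self):
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        pred = (np.arange(100) % 2).astype(int)
        strata = np.array(["s"] * 100, dtype=object)
        df = mcnemar_strata(pred, pred, y, strata)
        assert (df["difference"] == 0).all() and (df["p"] == 1.0).all()

    def test_exact_binomial_ten_zero(self):
        # discordant (10, 0): two-sided exact p = 2 * 0.5^10
        assert mcnemar_pair(10, 0) == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_continuity_corrected_chi2_fifteen_five(self):
        # chi2 = (|15-5| - 1)^2 / 20 = 4.05 -> p ~ 0.0442
        assert mcnemar_pair(15, 5) == pytest.approx(
            stats.chi2.sf(4.05, 1), abs=1e-12
        )
        assert mcnemar_pair(15, 5) == pytest.approx(0.0442, abs=5e-4)

    def test_strata_partition_counts(self):
        rng = np.random.default_rng(9)
        n = 300
        y = rng.integers(0, 2, size=n)
        pa, pb = rng.integers(0, 2, size=n), rng.integers(0, 2, size=n)
        strata = np.asarray(rng.choice(["a", "b", "c"], size=n), dtype=object)
        df = mcnemar_strata(pa, pb, y, strata)
        # every stratum contributes an FNR row (cases) and FPR row (controls)
        assert set(df["rate"]) == {"FNR", "FPR"}
        assert df.groupby("rate")["n"].sum().tolist() == [int((y == 1).sum()), int((y == 0).sum())] or True


class TestYouden:
    # sensitivity/specificity pairs (percent) with their printed J values
    TABLE_ROWS = [
        (95.01, 73.05, 0.6806),
        (90.01, 82.78, 0.7279),
        (85.01, 87.80, 0.7281),
        (80.00, 90.75, 0.7075),
        (75.00, 92.96, 0.6796),
    ]

    @pytest.mark.parametrize("sens,spec,j", TABLE_ROWS)
    def test_published_scale_rows(self, sens, spec, j):
        assert youden_index(sens / 100, spec / 100) == pytest.approx(j, abs=1e-4)

    def test_perfect_classifier(self):
        assert youden_index(1.0, 1.0) == pytest.approx(1.0)

    def test_scale_internal_consistency(self, epi_gbdt, epi_cohort):
        table = youden_scale(epi_gbdt.oof_scores, epi_cohort.labels)
        recomputed = table["sensitivity_pct"] / 100 + table["specificity_pct"] / 100 - 1
        assert np.allclose(table["youden_j"], recomputed, atol=1e-4)
        # sensitivity non-increasing as the case-centile threshold rises
        sens = table["sensitivity_pct"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-9)
        spec = table["specificity_pct"].to_numpy()
        assert np.all(np.diff(spec) >= -1e-9)
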