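"""Association module: Firth solver oracles, IVW meta, clumping rules and
stepwise conditional signal discovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

from t1grs_lab.assoc import (
    AssocResult,
    build_precondition_covariates,
    clump_and_define_loci,
    firth_logistic,
    ivw_meta,
    logistic_scan,
    stepwise_conditional,
)
from t1grs_lab.cohort import EffectSpec, VariantSpec
from t1grs_lab.simulate import simulate_genotypes, simulate_phenotypes


def _panel(n, maf=0.3, blocks=None):
    return [
        VariantSpec(id=f"v{i}", chrom="1", pos=10 * (i + 1), ref="A", alt="G",
                    maf=maf, block_id=i if blocks is None else blocks[i])
        for i in range(n)
    ]


class TestFirth:
    def test_permuted_labels_p_uniform(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 3, size=500).astype(float)
        y = rng.integers(0, 2, size=500)
        pvals = []
        for _ in range(200):
            yp = rng.permutation(y)
            pvals.append(firth_logistic(yp, x).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_complete_separation_stays_finite(self):
        # all 20 cases carry the alt allele, no control does: ML diverges,
        # the Jeffreys penalty does not
        y = np.r_[np.ones(20), np.zeros(180)]
        x = np.r_[np.ones(20), np.zeros(180)]
        r = firth_logistic(y, x)
        assert np.isfinite(r.beta) and np.isfinite(r.se)
        assert r.beta > 0

    def test_matches_direct_penalized_likelihood_maximization(self):
        # collapsed 2x2 toy: independent oracle maximizes the penalized
        # likelihood written from scratch
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]

        def neg_pen_ll(b):
            eta = b[0] + b[1] * x
            p = expit(eta)
            ll = np.sum(y * eta - np.logaddexp(0, eta))
            X = np.column_stack([np.ones_like(x), x])
            W = p * (1 - p)
            sign, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
            return -(ll + 0.5 * logdet)

        res = minimize(neg_pen_ll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        r = firth_logistic(y, x)
        assert abs(r.beta - res.x[1]) < 1e-4

    def test_randomized_separated_datasets_finite(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            x = rng.integers(0, 3, size=n).astype(float)
            if np.ptp(x) == 0:
                continue
            y = (x >= rng.integers(1, 3)).astype(float)  # perfectly separated
            if y.min() == y.max():
                continue
            r = firth_logistic(y, x)
            assert np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0

    def test_zero_variance_dosage_errors(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="zero-variance"):
            firth_logistic(y, np.ones(10))

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=100)
        x = rng.integers(0, 3, size=100).astype(float)
        covars = pd.DataFrame({"a": rng.normal(size=100)})
        covars["b"] = 2 * covars["a"]
        with pytest.raises(ValueError, match="b"):
            firth_logistic(y, x, covars=covars)

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            AssocResult("v", beta=1.0, se=0.0, z=0.0, p=0.5, af=0.1, n=10)
        with pytest.raises(ValueError):
            AssocResult("v", beta=1.0, se=0.5, z=1.0, p=0.5, af=0.1, n=10)


class TestLogisticScan:
    def test_agrees_with_firth_for_common_variants(self):
        panel = _panel(5)
        G = simulate_genotypes(panel, 4000, ld_rho=0.0, seed=3)
        eff = EffectSpec(additive={"v0": 0.4}, intercept=float(logit(0.3)))
        y = simulate_phenotypes(G, panel, eff, seed=3).astype(float)
        beta, se = logistic_scan(y, G.astype(float))
        for j in range(5):
            r = firth_logistic(y, G[:, j])
            assert abs(beta[j] - r.beta) < 0.02
            assert abs(se[j] - r.se) < 0.01


class TestIvwMeta:
    def _res(self, beta, se, n=1000, vid="v"):
        return AssocResult(vid, beta=beta, se=se, z=beta / se,
                           p=2 * stats.norm.sf(abs(beta / se)), af=0.2, n=n)

    def test_symmetric_cohorts(self):
        m = ivw_meta([self._res(0.5, 0.1), self._res(0.5, 0.1)])
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-9)

    def test_single_cohort_identity(self):
        r = self._res(0.3, 0.15)
        m = ivw_meta([r])
        assert m.beta == pytest.approx(r.beta) and m.se == pytest.approx(r.se)

    def test_hand_calculation(self):
        # w = (100, 25): beta = (20+15)/125 = 0.28, se = 1/sqrt(125)
        m = ivw_meta([self._res(0.2, 0.1), self._res(0.6, 0.2)])
        assert m.beta == pytest.approx(0.28, abs=1e-12)
        assert m.se == pytest.approx(0.0894427, abs=1e-6)

    def test_se_invariant(self):
        m = ivw_meta([self._res(0.2, 0.1), self._res(0.6, 0.2)])
        assert abs(m.se - (sum(se**-2 for se in (0.1, 0.2))) ** -0.5) < 1e-10

    def test_adding_cohort_never_increases_se(self):
        rng = np.random.default_rng(2)
        rs = [self._res(0.2, float(se)) for se in rng.uniform(0.05, 0.5, size=6)]
        ses = [ivw_meta(rs[: k + 1]).se for k in range(len(rs))]
        assert all(b <= a + 1e-12 for a, b in zip(ses, ses[1:]))

    def test_mismatched_variants_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            ivw_meta([self._res(0.2, 0.1, vid="a"), self._res(0.2, 0.1, vid="b")])


class TestClumping:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])

    def test_single_significant_variant_single_locus(self):
        meta = self._meta(
            [("a", "1", 1_000_000, 1e-10), ("b", "1", 1_050_000, 0.2), ("c", "1", 2_000_000, 0.5)]
        )
        ld = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        loci = clump_and_define_loci(meta, ld)
        assert len(loci) == 1
        assert loci[0].index_id == "a"
        assert loci[0].start == 1_000_000 - 500_000 and loci[0].end == 1_000_000 + 500_000

    def test_two_linked_significant_variants_one_clump(self):
        meta = self._meta([("a", "1", 1_000_000, 1e-10), ("b", "1", 1_010_000, 1e-9)])
        ld = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("ab"), columns=list("ab"))
        loci = clump_and_define_loci(meta, ld)
        assert len(loci) == 1
        assert loci[0].index_id == "a"  # smaller p
        assert set(loci[0].members) == {"a", "b"}

    def test_no_significant_variants_empty(self):
        meta = self._meta([("a", "1", 100, 1e-6), ("b", "1", 200, 0.3)])
        ld = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        assert clump_and_define_loci(meta, ld) == []

    def test_round_two_merges_nearby_linked_indices(self):
        # both survive round 1 (r2 = 0.05 < 0.1) but merge in round 2 (r2 > 0)
        meta = self._meta([("a", "1", 1_000_000, 1e-10), ("b", "1", 1_200_000, 1e-9)])
        ld = pd.DataFrame([[1.0, 0.05], [0.05, 1.0]], index=list("ab"), columns=list("ab"))
        loci = clump_and_define_loci(meta, ld)
        assert len(loci) == 1 and loci[0].index_id == "a"


class TestStepwiseConditional:
    def _simulate_region(self, betas, n=12_000, rho=0.0, seed=0, blocks=None):
        panel = _panel(len(betas) if not isinstance(betas, dict) else 10,
                       blocks=blocks)
        G = simulate_genotypes(panel, n, ld_rho=rho, seed=seed)
        eff = EffectSpec(
            additive={f"v{i}": b for i, b in enumerate(betas) if b != 0},
            intercept=float(logit(0.3)),
        )
        y = simulate_phenotypes(G, panel, eff, seed=seed)
        return y, G, [v.id for v in panel]

    def test_two_independent_signals_recovered(self):
        b = np.log(1.6)
        y, G, ids = self._simulate_region([b, 0, 0, b, 0, 0], seed=8)
        signals = stepwise_conditional([(y, G)], ids)
        assert len(signals) == 2
        assert {s.lead for s in signals} == {"v0", "v3"}
        assert [s.rank for s in signals] == [1, 2]

    def test_shadow_variant_yields_single_signal(self):
        # v0 causal; v1 in the same block at high LD is only a shadow
        y, G, ids = self._simulate_region(
            [np.log(1.8), 0], rho=0.998, seed=9, blocks=[0, 0]
        )
        r2 = np.corrcoef(G.T)[0, 1] ** 2
        assert r2 > 0.8
        signals = stepwise_conditional([(y, G)], ids)
        assert len(signals) == 1

    def test_null_region_empty(self):
        y, G, ids = self._simulate_region([0, 0, 0, 0], n=4000, seed=10)
        assert stepwise_conditional([(y, G)], ids) == []

    def test_conditioning_set_grows_in_order(self):
        b = np.log(1.7)
        y, G, ids = self._simulate_region([b, 0, b, 0], seed=11)
        signals = stepwise_conditional([(y, G)], ids)
        for i, s in enumerate(signals):
            assert len(s.conditioning_set) == i
            assert s.p < 5e-8


class TestPreconditionCovariates:
    def test_column_count_70_plus_20(self):
        panel = _panel(100)
        G = simulate_genotypes(panel, 200, seed=1)
        ids = [v.id for v in panel]
        alleles = ids[:70]
        pairs = [(ids[70 + i], ids[80 + i]) for i in range(10)] + [
            (ids[90 + i], ids[i]) for i in range(10)
        ]
        cov = build_precondition_covariates(G, ids, alleles, pairs)
        assert cov.shape[1] == 90

    def test_interaction_column_binary(self):
        panel = _panel(4)
        G = simulate_genotypes(panel, 300, seed=2)
        ids = [v.id for v in panel]
        cov = build_precondition_covariates(G, ids, [], [("v0", "v1")])
        assert set(np.unique(cov["v0:v1"])) <= {0.0, 1.0}

    def test_noncarrier_pair_entry_zero(self):
        G = np.array([[0, 2], [2, 2]], dtype=np.int8)
        cov = build_precondition_covariates(G, ["a", "b"], [], [("a", "b")])
        assert cov["a:b"].tolist() == [0.0, 1.0]

    def test_unknown_tag_errors(self):
        with pytest.raises(KeyError, match="nope"):
            build_precondition_covariates(np.zeros((2, 1), dtype=np.int8), ["a"], ["nope"], [])
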