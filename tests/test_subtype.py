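"""Subtype discovery: embedding, Leiden clustering, archetype recovery,
validation projection and the clinical contrast statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from t1grs_lab.simulate import simulate_shap_archetypes
from t1grs_lab.subtype import (
    celltype_enrichment,
    choose_k,
    cluster,
    cluster_feature_stats,
    complication_assoc,
    embed,
    layout_2d,
    onset_logrank,
    project_validation,
    t2d_enrichment,
    top_cluster_loci,
)


@pytest.fixture(scope="module")
def archetypes():
    mat, labels = simulate_shap_archetypes(n=1200, n_features=40, k=4, seed=8)
    return mat, labels


@pytest.fixture(scope="module")
def arch_embedding(archetypes):
    mat, _ = archetypes
    return embed(mat, n_pcs=30, k=30, seed=0)


class TestEmbed:
    def test_pc_count_capped(self):
        mat, _ = simulate_shap_archetypes(n=50, n_features=10, k=2, seed=1)
        emb = embed(mat, n_pcs=175, k=120, seed=0)
        assert emb.pcs.shape[1] <= 10
        assert emb.knn_indices.shape[1] == 49  # k capped at n-1

    def test_no_self_edges(self, arch_embedding):
        n = arch_embedding.pcs.shape[0]
        for i in range(0, n, 97):
            assert i not in arch_embedding.knn_indices[i]

    def test_separated_archetypes_rarely_linked(self, archetypes, arch_embedding):
        _, labels = archetypes
        neigh_labels = labels[arch_embedding.knn_indices]
        cross = (neigh_labels != labels[:, None]).mean()
        assert cross < 0.05

    def test_deterministic(self, archetypes):
        mat, _ = archetypes
        e1 = embed(mat, n_pcs=10, k=15, seed=0)
        e2 = embed(mat, n_pcs=10, k=15, seed=0)
        assert np.allclose(e1.pcs, e2.pcs)
        assert np.array_equal(e1.knn_indices, e2.knn_indices)


class TestCluster:
    def test_recovers_planted_archetypes(self, archetypes, arch_embedding):
        _, labels = archetypes
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        assert adjusted_rand_score(labels, ca.labels) >= 0.9

    def test_resolution_to_zero_single_cluster(self, arch_embedding):
        ca = cluster(arch_embedding, resolution=1e-6, seed=0)
        assert ca.n_clusters == 1

    def test_labels_canonical_by_size(self, arch_embedding):
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        sizes = np.bincount(ca.labels)
        assert np.all(np.diff(sizes) <= 0)
        assert set(ca.labels) == set(range(ca.n_clusters))

    def test_ari_invariant_to_label_permutation(self, archetypes, arch_embedding):
        _, labels = archetypes
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        perm = (ca.labels + 1) % (ca.labels.max() + 1)
        assert adjusted_rand_score(labels, ca.labels) == pytest.approx(
            adjusted_rand_score(labels, perm)
        )


class TestChooseK:
    def test_planted_k_optimal(self, arch_embedding):
        k, diag = choose_k(arch_embedding, seed=0)
        assert k == 4
        assert diag["silhouette"].notna().any()

    def test_inertia_decreases_with_k(self, arch_embedding):
        _, diag = choose_k(arch_embedding, seed=0)
        d = diag.dropna(subset=["silhouette"]).sort_values("k")
        by_k = d.groupby("k")["inertia"].mean()
        if len(by_k) > 1:
            assert by_k.is_monotonic_decreasing


class TestLayout:
    def test_shape_and_separation(self, archetypes, arch_embedding):
        _, labels = archetypes
        xy = layout_2d(arch_embedding, min_dist=0.25, seed=0)
        assert xy.shape == (len(labels), 2)
        centroids = np.array([xy[labels == a].mean(axis=0) for a in range(4)])
        within = np.mean(
            [np.linalg.norm(xy[labels == a] - centroids[a], axis=1).mean() for a in range(4)]
        )
        between = np.mean(
            [
                np.linalg.norm(centroids[a] - centroids[b])
                for a in range(4)
                for b in range(a + 1, 4)
            ]
        )
        assert between / within > 2.0


class TestProjection:
    def test_self_projection_consistent(self, archetypes, arch_embedding):
        mat, _ = archetypes
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        labels, dists = project_validation(mat, arch_embedding, ca.labels)
        assert (labels == ca.labels).mean() > 0.99

    def test_validation_cohort_matches_proportions(self, archetypes, arch_embedding):
        mat, truth = archetypes
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        vmat, vtruth = simulate_shap_archetypes(n=800, n_features=40, k=4, seed=99)
        vlabels, table = project_validation(vmat, arch_embedding, ca.labels)
        disc_prop = np.bincount(ca.labels, minlength=4) / len(ca.labels)
        val_prop = np.bincount(vlabels, minlength=4) / len(vlabels)
        assert np.abs(disc_prop - val_prop).max() < 0.05
        assert adjusted_rand_score(vtruth, vlabels) >= 0.9

    def test_empty_validation(self, arch_embedding, archetypes):
        _, labels = archetypes
        ca = cluster(arch_embedding, resolution=0.05, seed=0)
        out, table = project_validation(np.empty((0, 40)), arch_embedding, ca.labels)
        assert len(out) == 0


class TestFeatureStats:
    def test_identical_feature_zero_lfc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        X[:, 0] = 1.0
        labels = rng.integers(0, 2, size=200)
        df = cluster_feature_stats(X, ["a", "b", "c"], labels)
        assert df.loc[df["feature"] == "a", "log2fc"].abs().max() < 1e-9

    def test_planted_dominant_feature(self, archetypes):
        mat, labels = archetypes
        df = cluster_feature_stats(mat, [f"f{j}" for j in range(40)], labels)
        # archetype 0's dominant features are f0..f3
        sub = df[(df["cluster"] == 0) & (df["feature"] == "f0")]
        assert sub["log2fc"].iloc[0] > 0.5
        assert sub["p"].iloc[0] < 0.01

    def test_two_cluster_antisymmetry(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(size=(100, 2)))
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        df = cluster_feature_stats(X, ["a", "b"], labels)
        a0 = df[(df.cluster == 0) & (df.feature == "a")]["log2fc"].iloc[0]
        a1 = df[(df.cluster == 1) & (df.feature == "a")]["log2fc"].iloc[0]
        assert a0 == pytest.approx(-a1, abs=1e-9)


class TestTopLoci:
    def test_equal_split_unassigned(self):
        X = np.ones((80, 1))
        labels = np.repeat(np.arange(4), 20)
        out = top_cluster_loci(X, ["f"], labels)
        assert all(len(v) == 0 for v in out.values())

    def test_dominant_share_assigned(self):
        labels = np.repeat(np.arange(4), 25)
        X = np.full((100, 1), 0.1)
        X[labels == 2, 0] = 5.0
        out = top_cluster_loci(X, ["f"], labels)
        assert out[2] == ["f"]

    def test_assignments_unique(self, archetypes):
        mat, labels = archetypes
        out = top_cluster_loci(np.abs(mat), [f"f{j}" for j in range(40)], labels)
        seen: list[str] = []
        for v in out.values():
            seen.extend(v)
        assert len(seen) == len(set(seen))


class TestCelltypeEnrichment:
    def _setup(self):
        # cluster 0's credible-set variants all map to T cells; the wider
        # annotation table carries many variants across four cell types so the
        # permutation null is informative
        top = {0: ["locus_a"], 1: ["locus_b"]}
        pips = {
            "locus_a": {f"a{i}": 0.2 for i in range(5)},
            "locus_b": {"b0": 0.5, "b1": 0.4},
        }
        ann = {f"a{i}": "T_cell" for i in range(5)}
        ann.update({"b0": "islet", "b1": "NK"})
        rng = np.random.default_rng(0)
        for i in range(40):
            ann[f"x{i}"] = str(rng.choice(["T_cell", "islet", "NK", "B_cell"]))
        return top, pips, ann

    def test_planted_enrichment_detected(self):
        top, pips, ann = self._setup()
        df = celltype_enrichment(top, pips, ann, n_perm=500, seed=0)
        row = df[(df.cluster == 0) & (df.cell_type == "T_cell")]
        assert row["p"].iloc[0] < 0.01

    def test_p_never_zero(self):
        top, pips, ann = self._setup()
        df = celltype_enrichment(top, pips, ann, n_perm=200, seed=1)
        assert (df["p"] >= 1 / 201).all()

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(40):
            variants = {f"v{i}": float(rng.uniform(0.1, 1)) for i in range(12)}
            pips = {"locus": variants}
            ann = {v: str(rng.choice(["A", "B", "C"])) for v in variants}
            df = celltype_enrichment({0: ["locus"]}, pips, ann, n_perm=99, seed=int(rng.integers(2**31)))
            pvals.extend(df["p"].tolist())
        # permutation p-values under the null are super-uniform at worst;
        # check they are not concentrated at small values
        assert np.mean(np.asarray(pvals) < 0.05) < 0.15


class TestOnsetLogrank:
    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            onset_logrank(np.ones(10), np.zeros(10))

    def test_null_not_significant_in_expectation(self):
        rng = np.random.default_rng(6)
        p = [
            onset_logrank(rng.normal(15, 5, size=200).clip(0.1),
                          rng.integers(0, 2, size=200))["p"]
            for _ in range(30)
        ]
        assert np.mean(np.asarray(p) < 0.05) < 0.25


class TestComplicationAssoc:
    def test_zero_cell_continuity_corrected(self):
        events = np.r_[np.ones(10), np.zeros(10)].astype(int)
        clusters = np.r_[np.zeros(10), np.ones(10)].astype(int)
        res = complication_assoc(events, clusters, 0)
        assert res["continuity_corrected"]
        assert np.isfinite(res["odds_ratio"])

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(100):
            events = rng.integers(0, 2, size=400)
            clusters = rng.integers(0, 2, size=400)
            res = complication_assoc(events, clusters, 0)
            covered += res["ci_low"] <= 1.0 <= res["ci_high"]
        assert covered >= 90

    def test_cox_p_reported_with_onset(self):
        rng = np.random.default_rng(8)
        events = rng.integers(0, 2, size=300)
        clusters = rng.integers(0, 2, size=300)
        onset = rng.normal(15, 5, size=300).clip(0.5)
        res = complication_assoc(events, clusters, 0, onset=onset)
        assert "cox_p" in res


class TestT2dEnrichment:
    def test_independent_labels_small_coefficient(self):
        rng = np.random.default_rng(9)
        shares = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=60),
            index=[f"locus{i}" for i in range(60)],
            columns=[0, 1, 2, 3],
        )
        labels = {f"locus{i}": int(rng.integers(0, 2)) for i in range(60)}
        df = t2d_enrichment(shares, labels)
        assert (df["p"] > 0.01).all()

    def test_planted_enrichment_positive(self):
        rng = np.random.default_rng(10)
        n = 80
        share0 = rng.uniform(0, 1, size=n)
        labels = {f"l{i}": int(rng.random() < 0.15 + 0.7 * share0[i]) for i in range(n)}
        shares = pd.DataFrame(
            {0: share0, 1: (1 - share0) / 3, 2: (1 - share0) / 3, 3: (1 - share0) / 3},
            index=[f"l{i}" for i in range(n)],
        )
        df = t2d_enrichment(shares, labels)
        assert df[df.cluster == 0]["log_or"].iloc[0] > 0

    def test_degenerate_outcome_errors(self):
        shares = pd.DataFrame({0: [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError):
            t2d_enrichment(shares, {"a": 1, "b": 1})
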