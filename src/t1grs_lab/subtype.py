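"""SHAP-space genetic subtyping and clinical characterization.

Individuals are embedded by PCA of their attribution vectors (up to 175
components), connected in a k-nearest-neighbor graph (k = 120) and clustered
with the Leiden community-detection algorithm at resolution 0.05; a UMAP
layout (min_dist 0.25) is presentation-only. Validation cohorts are projected
with the discovery PCA loadings and assigned by kNN majority vote against the
discovery individuals. Downstream characterization covers per-cluster feature
statistics, top-locus assignment by normalized attribution share, cell-type
regulatory-element permutation enrichment, age-of-onset log-rank tests,
complication odds ratios and a T2D-locus enrichment regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .assoc import firth_logistic


@dataclass
class EmbeddingResult:
    pcs: np.ndarray  # n x n_pcs
    loadings: np.ndarray  # n_pcs x p
    mean: np.ndarray  # feature means used for centering
    explained_variance_ratio: np.ndarray
    knn_indices: np.ndarray  # n x k (no self)
    knn_distances: np.ndarray
    k: int


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    k: int = 0
    diagnostics: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def embed(shap_values: np.ndarray, n_pcs: int = 175, k: int = 120, seed: int = 0) -> EmbeddingResult:
    """PCA of centered attribution vectors plus a Euclidean kNN graph in PC
    space. ``n_pcs`` is capped at min(n-1, p); ``k`` at n-1."""
    X = np.asarray(shap_values, dtype=float)
    n, p = X.shape
    n_pcs = int(min(n_pcs, n - 1, p)) if n > 1 else 1
    k = int(min(k, n - 1))
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    return EmbeddingResult(
        pcs=pcs, loadings=pca.components_, mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        knn_indices=idx[:, 1:], knn_distances=dist[:, 1:], k=k,
    )


def _knn_graph(emb: EmbeddingResult) -> ig.Graph:
    n, k = emb.knn_indices.shape
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in emb.knn_indices[i]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    g.simplify()
    return g


def cluster(emb: EmbeddingResult, resolution: float = 0.05, seed: int = 0) -> ClusterAssignment:
    """Leiden community detection on the kNN graph.

    Uses the RB-configuration quality function (resolution-parameterized
    modularity); labels are canonicalized by descending cluster size so reruns
    and cross-run comparisons are stable."""
    g = _knn_graph(emb)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[x] for x in raw])
    return ClusterAssignment(labels=labels, resolution=resolution, k=emb.k)


def choose_k(
    emb: EmbeddingResult,
    resolutions: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5),
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Sweep resolutions; score each induced k by silhouette (PC space) and
    within-cluster inertia. Returns the silhouette-optimal k (k = 1 solutions
    carry no silhouette and are excluded) with the diagnostics table."""
    rows = []
    for res in resolutions:
        ca = cluster(emb, resolution=res, seed=seed)
        kk = ca.n_clusters
        inertia = 0.0
        for c in range(kk):
            sub = emb.pcs[ca.labels == c]
            inertia += float(((sub - sub.mean(axis=0)) ** 2).sum())
        sil = np.nan
        if 1 < kk < len(ca.labels):
            sil = float(silhouette_score(emb.pcs, ca.labels))
        rows.append({"resolution": res, "k": kk, "silhouette": sil, "inertia": inertia})
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["silhouette"])
    if valid.empty:
        return 1, df
    best = valid.loc[valid["silhouette"].idxmax()]
    return int(best["k"]), df


def layout_2d(emb: EmbeddingResult, min_dist: float = 0.25, seed: int = 0) -> np.ndarray:
    """UMAP layout of the PC scores (presentation only)."""
    import umap

    reducer = umap.UMAP(min_dist=min_dist, random_state=seed, n_components=2)
    return np.asarray(reducer.fit_transform(emb.pcs))


def project_validation(
    validation_shap: np.ndarray,
    emb: EmbeddingResult,
    discovery_labels: np.ndarray,
    k: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign validation individuals to discovery clusters.

    Validation attribution vectors are centered with the discovery feature
    means and projected through the discovery loadings; each is assigned the
    majority cluster of its k nearest discovery neighbors in PC space (ties
    break toward the nearest neighbor's cluster). Returns labels and a
    per-cluster centroid-distance table."""
    V = np.asarray(validation_shap, dtype=float)
    if V.shape[0] == 0:
        return np.empty(0, dtype=int), pd.DataFrame(columns=["cluster", "n", "centroid_distance"])
    pcs_v = (V - emb.mean) @ emb.loadings.T
    k = emb.k if k is None else int(min(k, emb.pcs.shape[0]))
    nn = NearestNeighbors(n_neighbors=k).fit(emb.pcs)
    dist, idx = nn.kneighbors(pcs_v)
    labels = np.empty(len(V), dtype=int)
    for i in range(len(V)):
        votes = discovery_labels[idx[i]]
        counts = np.bincount(votes)
        winners = np.flatnonzero(counts == counts.max())
        labels[i] = winners[0] if len(winners) == 1 else discovery_labels[idx[i, 0]]
    rows = []
    for c in np.unique(discovery_labels):
        centroid = emb.pcs[discovery_labels == c].mean(axis=0)
        mine = pcs_v[labels == c]
        d = float(np.linalg.norm(mine - centroid, axis=1).mean()) if len(mine) else np.nan
        rows.append({"cluster": int(c), "n": int((labels == c).sum()), "centroid_distance": d})
    return labels, pd.DataFrame(rows)


def cluster_feature_stats(
    shap_values: np.ndarray, feature_names: list[str], labels: np.ndarray
) -> pd.DataFrame:
    """Per cluster x feature: log2 fold-change of the mean absolute
    attribution inside vs outside the cluster, with a two-sided t-test on the
    raw attributions (both raw and BH-adjusted p reported)."""
    X = np.asarray(shap_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    eps = 1e-12
    for c in np.unique(labels):
        inside = labels == c
        for j, f in enumerate(feature_names):
            a, b = X[inside, j], X[~inside, j]
            lfc = float(np.log2((np.abs(a).mean() + eps) / (np.abs(b).mean() + eps)))
            if len(a) > 1 and len(b) > 1 and (a.std() > 0 or b.std() > 0):
                _, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                p = np.nan
            rows.append({"cluster": int(c), "feature": f, "log2fc": lfc, "p": float(p)})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df


def top_cluster_loci(
    shap_values: np.ndarray,
    feature_names: list[str],
    labels: np.ndarray,
    threshold: float = 0.75,
) -> dict[int, list[str]]:
    """Assign features to clusters by normalized attribution share.

    Mean absolute attribution per cluster is normalized per feature to sum to
    1 across clusters; a feature belongs to a cluster iff its share exceeds
    the threshold (> 0.5 guarantees uniqueness)."""
    X = np.abs(np.asarray(shap_values, dtype=float))
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    means = np.vstack([X[labels == c].mean(axis=0) for c in clusters])  # k x p
    shares = means / np.maximum(means.sum(axis=0, keepdims=True), 1e-300)
    out: dict[int, list[str]] = {int(c): [] for c in clusters}
    for j, f in enumerate(feature_names):
        top = int(np.argmax(shares[:, j]))
        if shares[top, j] > threshold:
            out[int(clusters[top])].append(f)
    return out


def celltype_enrichment(
    top_loci: dict[int, list[str]],
    credible_pips: dict[str, dict[str, float]],
    annotation: dict[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of cell-type regulatory enrichment per cluster.

    ``credible_pips`` maps locus -> {variant: PIP}; ``annotation`` maps
    variant -> cell type. For each cluster and cell type the observed
    statistic is the summed PIP of the cluster's credible-set variants
    annotated to that cell type. The null permutes the annotation table's
    cell-type labels across *all* annotated variants and recomputes the
    cluster's sums, with the add-one estimator
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``."""
    rng = np.random.default_rng(seed)
    cell_types = sorted(set(annotation.values()))
    ann_variants = sorted(annotation)
    ann_labels = np.asarray([annotation[v] for v in ann_variants], dtype=object)
    ann_index = {v: i for i, v in enumerate(ann_variants)}
    rows = []
    for c, loci in sorted(top_loci.items()):
        variants, pips = [], []
        for locus in loci:
            for v, pip in credible_pips.get(locus, {}).items():
                if v in ann_index:
                    variants.append(v)
                    pips.append(pip)
        pips_arr = np.asarray(pips, dtype=float)
        vidx = np.asarray([ann_index[v] for v in variants], dtype=int)
        labels = ann_labels[vidx] if len(vidx) else np.empty(0, dtype=object)
        observed = {
            ct: float(pips_arr[labels == ct].sum()) if len(pips_arr) else 0.0
            for ct in cell_types
        }
        null_counts = {ct: 0 for ct in cell_types}
        for _ in range(n_perm):
            perm_all = rng.permutation(ann_labels)
            perm = perm_all[vidx] if len(vidx) else labels
            for ct in cell_types:
                stat = float(pips_arr[perm == ct].sum()) if len(pips_arr) else 0.0
                if stat >= observed[ct] - 1e-12:
                    null_counts[ct] += 1
        for ct in cell_types:
            rows.append(
                {
                    "cluster": c, "cell_type": ct, "observed": observed[ct],
                    "p": (1 + null_counts[ct]) / (n_perm + 1), "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


def onset_logrank(onset: np.ndarray, cluster_labels: np.ndarray) -> dict:
    """Multivariate log-rank test of onset-age curves across clusters.

    Onset ages are treated as fully observed events. Returns the test
    statistic, p-value and per-cluster median onset. A single cluster is an
    error (no contrast)."""
    onset = np.asarray(onset, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    ok = ~np.isnan(onset)
    onset, cluster_labels = onset[ok], cluster_labels[ok]
    if len(np.unique(cluster_labels)) < 2:
        raise ValueError("log-rank requires at least two clusters")
    res = multivariate_logrank_test(onset, cluster_labels, np.ones_like(onset))
    medians = {
        str(c): float(np.median(onset[cluster_labels == c])) for c in np.unique(cluster_labels)
    }
    return {"chi2": float(res.test_statistic), "p": float(res.p_value), "median_onset": medians}


def complication_assoc(
    events: np.ndarray,
    cluster_labels: np.ndarray,
    cluster: int | str,
    onset: np.ndarray | None = None,
) -> dict:
    """Cluster-vs-rest complication odds ratio with Woolf 95% CI.

    Builds the 2x2 table of complication events for the chosen cluster
    against all others; zero cells get the Haldane 0.5 correction (flagged).
    Two-sided p from Fisher's exact test; when onset times are supplied a Cox
    proportional-hazards p for cluster membership is added."""
    events = np.asarray(events, dtype=int)
    inc = np.asarray(cluster_labels) == cluster
    a = int(np.sum(inc & (events == 1)))
    b = int(np.sum(inc & (events == 0)))
    c = int(np.sum(~inc & (events == 1)))
    d = int(np.sum(~inc & (events == 0)))
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    _, p = stats.fisher_exact([[a, b], [c, d]])
    out = {
        "odds_ratio": float(or_), "ci_low": float(lo), "ci_high": float(hi),
        "p": float(p), "table": (a, b, c, d), "continuity_corrected": corrected,
    }
    if onset is not None:
        onset = np.asarray(onset, dtype=float)
        ok = ~np.isnan(onset)
        df = pd.DataFrame(
            {"duration": onset[ok], "event": events[ok], "in_cluster": inc[ok].astype(int)}
        )
        try:
            cph = CoxPHFitter().fit(df, duration_col="duration", event_col="event")
            out["cox_p"] = float(cph.summary.loc["in_cluster", "p"])
        except Exception:
            out["cox_p"] = np.nan
    return out


def t2d_enrichment(
    locus_shap: pd.DataFrame,
    t2d_labels: dict[str, int],
) -> pd.DataFrame:
    """Per-cluster regression of T2D-locus status on attribution share.

    ``locus_shap``: loci x clusters mean-normalized attribution (each row the
    per-cluster share for one locus). For each cluster a penalized logistic
    regression of the binary T2D label on that cluster's shares gives the
    enrichment log-OR and p. All-same-label outcomes are an error."""
    y = np.array([t2d_labels[locus] for locus in locus_shap.index], dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all loci share the same T2D label")
    rows = []
    for col in locus_shap.columns:
        x = locus_shap[col].to_numpy(dtype=float)
        res = firth_logistic(y, x, variant_id=str(col))
        rows.append(
            {"cluster": col, "log_or": res.beta, "odds_ratio": float(np.exp(res.beta)),
             "se": res.se, "p": res.p}
        )
    return pd.DataFrame(rows)
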