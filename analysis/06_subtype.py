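"""SHAP-space genetic subtyping of cases with clinical characterization:
embedding + Leiden clustering of attribution vectors, validation projection,
per-cluster feature statistics, top-locus assignment, cell-type enrichment,
onset log-rank and complication odds ratios.

Outputs: results/clusters.tsv, results/cluster_report.json,
         results/cluster_features.tsv, results/enrichment.tsv
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from t1grs_lab import io
from t1grs_lab.interpret import compute_shap
from t1grs_lab.riskmodel import assemble_features, train_gbdt_cv
from t1grs_lab.subtype import (
    celltype_enrichment,
    choose_k,
    cluster,
    cluster_feature_stats,
    complication_assoc,
    embed,
    onset_logrank,
    project_validation,
    top_cluster_loci,
)

OUT = Path("results")
SEED = 33

if __name__ == "__main__":
    discovery = io.read_cohort(OUT / "cohorts" / "discovery")
    validation = io.read_cohort(OUT / "cohorts" / "validation")
    summary = io.read_summary_stats(OUT / "summary_stats.tsv")
    betas = dict(zip(summary["variant_id"], summary["beta"]))

    feats = assemble_features(discovery, betas=betas, submodel="ALL")
    gbdt = train_gbdt_cv(feats, discovery.labels, k=10, seed=SEED)
    shap = compute_shap(gbdt, feats.X, groups=feats.groups)

    cases = discovery.labels == 1
    emb = embed(shap.values[cases], n_pcs=175, k=120, seed=SEED)
    ca = cluster(emb, resolution=0.05, seed=SEED)
    k_opt, diag = choose_k(emb, seed=SEED)
    print(f"Leiden at resolution 0.05: {ca.n_clusters} clusters "
          f"(silhouette-optimal k = {k_opt})")

    pd.DataFrame(
        {"sample_id": discovery.samples.loc[cases, "sample_id"].to_numpy(),
         "cluster": ca.labels}
    ).to_csv(OUT / "clusters.tsv", sep="\t", index=False)

    vfeats = assemble_features(validation, betas=betas, submodel="ALL")
    vshap = compute_shap(gbdt, vfeats.X, groups=vfeats.groups, out_of_fold=False)
    vcases = validation.labels == 1
    vlabels, vtable = project_validation(vshap.values[vcases], emb, ca.labels)
    print("validation projection:")
    print(vtable.to_string(index=False))

    stats_df = cluster_feature_stats(shap.values[cases], shap.feature_names, ca.labels)
    stats_df.to_csv(OUT / "cluster_features.tsv", sep="\t", index=False)
    top = top_cluster_loci(shap.values[cases], shap.feature_names, ca.labels)
    annotation = {v.id: v.annotation for v in discovery.truth.panel if v.annotation}
    pips = {f: {f: 1.0} for loci in top.values() for f in loci}  # lead-variant PIPs
    enr = celltype_enrichment(top, pips, annotation, n_perm=2000, seed=SEED)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    report = {"n_clusters": ca.n_clusters, "k_optimal": int(k_opt),
              "top_loci": {str(k): v for k, v in top.items()},
              "validation": vtable.to_dict(orient="records")}
    onset = discovery.samples.loc[cases, "onset_age"].to_numpy(dtype=float)
    if ca.n_clusters > 1:
        report["onset_logrank"] = onset_logrank(onset, ca.labels)
        print(f"onset log-rank: chi2 {report['onset_logrank']['chi2']:.2f}, "
              f"p {report['onset_logrank']['p']:.3g}")
        report["complications"] = {}
        for comp in ("nephropathy", "neuropathy", "cvd", "retinopathy"):
            ev = discovery.samples.loc[cases, comp].to_numpy(dtype=int)
            report["complications"][comp] = {
                str(c): {k: v for k, v in
                         complication_assoc(ev, ca.labels, c).items() if k != "table"}
                for c in range(ca.n_clusters)
            }
    with open(OUT / "cluster_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    print(f"cluster report written to {OUT/'cluster_report.json'}")
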