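"""SHAP interpretation of the trained ensemble: global importance, pairwise
interaction significance, complexity scores and model performance across
complexity deciles.

Depends on 04_risk_model.py having been run (retrains the same fold split
from the serialized cohort to recover the models).

Outputs: results/importance.tsv, results/interactions.tsv,
         results/complexity.tsv, results/auc_by_complexity.tsv
"""

from pathlib import Path

import pandas as pd

from t1grs_lab import io
from t1grs_lab.interpret import (
    complexity_scores,
    compute_interactions,
    compute_shap,
    importance_ranking,
    interaction_significance,
    performance_by_complexity,
)
from t1grs_lab.riskmodel import assemble_features, train_gbdt_cv, train_logreg_cv

OUT = Path("results")
SEED = 33

if __name__ == "__main__":
    cohort = io.read_cohort(OUT / "cohorts" / "discovery")
    summary = io.read_summary_stats(OUT / "summary_stats.tsv")
    betas = dict(zip(summary["variant_id"], summary["beta"]))
    y = cohort.labels
    feats = assemble_features(cohort, betas=betas, submodel="ALL")
    gbdt = train_gbdt_cv(feats, y, k=10, seed=SEED)
    logreg = train_logreg_cv(feats, y, k=10, seed=SEED)

    shap = compute_shap(gbdt, feats.X, groups=feats.groups)
    imp = importance_ranking(shap)
    imp.to_csv(OUT / "importance.tsv", sep="\t", index=False)
    print("top features by mean |SHAP|:")
    print(imp.head(8).to_string(index=False))

    tensor = compute_interactions(gbdt, feats.X, groups=feats.groups,
                                  max_individuals=400, seed=SEED)
    inter = interaction_significance(tensor)
    inter.to_csv(OUT / "interactions.tsv", sep="\t", index=False)
    sig = inter[inter["significant_q05"]]
    print(f"\n{len(sig)} significant interactions at FDR 0.05:")
    if not sig.empty:
        print(sig[["feature_a", "feature_b", "z", "q", "category"]].to_string(index=False))
    print("planted pairs:", cohort.truth.effects.interactions)

    comp = complexity_scores(shap)
    comp.insert(0, "sample_id", cohort.samples["sample_id"].to_numpy())
    comp.to_csv(OUT / "complexity.tsv", sep="\t", index=False)
    perf = performance_by_complexity(
        {"gbdt": gbdt.oof_scores, "logreg": logreg.oof_scores},
        y, comp["decile"].to_numpy(),
    )
    perf.to_csv(OUT / "auc_by_complexity.tsv", sep="\t", index=False)
    print("\nAUC by complexity decile:")
    print(perf[["decile", "auc_gbdt", "auc_logreg", "auc_gap"]].to_string(index=False))
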