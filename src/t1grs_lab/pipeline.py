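"""End-to-end orchestration: simulate -> associate -> fine-map -> train ->
interpret -> subtype, from a single JSON-serializable config with one master
seed fanning out per stage, stage toggles, serialized interfaces between
stages and a manifest of output hashes for reproducibility audits."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seed
from . import assoc, finemap, interpret, io, riskmodel, simulate, subtype

STAGES = ("simulate", "assoc", "finemap", "train", "interpret", "subtype")


@dataclass
class PipelineConfig:
    """Validated run configuration. Defaults are the study conditions."""

    n: int = 5000
    n_mhc: int = 12
    n_nonmhc: int = 48
    ld_rho: float = 0.7
    seed: int = 0
    out_dir: str = "run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # association
    maf_min: float = assoc.MAF_MIN_GENOMEWIDE
    threshold: float = assoc.GW_THRESHOLD
    # fine-mapping
    abf_w: float = 0.04
    r2_threshold: float = 0.1
    mass: float = 0.95
    # model
    k_folds: int = 10
    gbdt_params: dict = field(default_factory=lambda: dict(riskmodel.GBDT_PARAMS))
    logreg_c: float = 0.001
    # interpretation
    fdr: float = 0.05
    max_interaction_individuals: int = 2000
    # subtyping
    n_pcs: int = 175
    knn_k: int = 120
    resolution: float = 0.05
    min_dist: float = 0.25
    n_perm: int = 10_000

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.validated(json.load(fh))

    @classmethod
    def validated(cls, d: dict) -> "PipelineConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        cfg = cls(**d)
        errors = []
        if cfg.n < 100:
            errors.append("n must be >= 100")
        if not (0 <= cfg.ld_rho < 1):
            errors.append("ld_rho must be in [0,1)")
        if not (0 < cfg.mass < 1):
            errors.append("mass must be in (0,1)")
        if cfg.abf_w <= 0:
            errors.append("abf_w must be positive")
        if set(cfg.stages) - set(STAGES):
            errors.append(f"unknown stages: {sorted(set(cfg.stages) - set(STAGES))}")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        for s in STAGES:
            cfg.stages.setdefault(s, True)
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    Each stage writes its outputs under the run directory before the next
    starts, and downstream stages consume only those serialized outputs plus
    in-memory handles documented here. Failures propagate with the stage
    named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    ctx: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config, out, ctx)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f.name: _hash_file(f) for f in files},
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _versions() -> dict:
    import sklearn
    import xgboost

    return {
        "numpy": np.__version__, "pandas": pd.__version__,
        "sklearn": sklearn.__version__, "xgboost": xgboost.__version__,
    }


def _stage_simulate(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    panel = simulate.make_panel(
        n_mhc=cfg.n_mhc, n_nonmhc=cfg.n_nonmhc, seed=child_seed(cfg.seed, "panel")
    )
    effects = simulate.default_effects(panel, seed=child_seed(cfg.seed, "effects"))
    cohort = simulate.simulate_cohort(
        n=cfg.n, panel=panel, effects=effects, ld_rho=cfg.ld_rho, seed=cfg.seed
    )
    d = io.write_cohort(cohort, out / "cohort")
    ctx["cohort"] = cohort
    return [d / "genotypes.vcf", d / "samples.tsv", d / "truth.json"]


def _stage_assoc(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    cohort = ctx.get("cohort") or io.read_cohort(out / "cohort")
    ctx["cohort"] = cohort
    covars = cohort.samples[["sex", "PC1", "PC2", "PC3", "PC4"]]
    results = assoc.association_scan(
        cohort.labels, cohort.dosage, cohort.variant_ids, covars=covars,
        maf_min=cfg.maf_min,
    )
    df = assoc.assoc_results_to_frame(results)
    pos = {v.id: (v.chrom, v.pos, v.ref, v.alt) for v in cohort.truth.panel}
    df["chrom"] = [pos[v][0] for v in df["variant_id"]]
    df["pos"] = [pos[v][1] for v in df["variant_id"]]
    df["ref"] = [pos[v][2] for v in df["variant_id"]]
    df["alt"] = [pos[v][3] for v in df["variant_id"]]
    io.write_summary_stats(df, out / "summary_stats.tsv")
    ctx["summary"] = df
    return [out / "summary_stats.tsv"]


def _stage_finemap(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    cohort = ctx["cohort"]
    df = ctx.get("summary")
    if df is None:
        df = io.read_summary_stats(out / "summary_stats.tsv")
    G = cohort.dosage.astype(float)
    ids = cohort.variant_ids
    r2 = pd.DataFrame(np.corrcoef(G.T) ** 2, index=ids, columns=ids)
    lead = df.loc[df["p"].idxmin(), "variant_id"]
    sub = df[df["variant_id"].isin(r2.index)]
    cs = finemap.finemap_signal(
        sub, r2, lead=lead,
        config=finemap.AbfConfig(W=cfg.abf_w, r2_threshold=cfg.r2_threshold, mass=cfg.mass),
        signal_id="lead_signal",
    )
    tbl = cs.table.copy()
    tbl.insert(0, "signal", cs.signal_id)
    tbl.to_csv(out / "credible_sets.tsv", sep="\t", index=False)
    ctx["credible_set"] = cs
    return [out / "credible_sets.tsv"]


def _stage_train(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    cohort = ctx["cohort"]
    summary = ctx.get("summary")
    betas = (
        dict(zip(summary["variant_id"], summary["beta"])) if summary is not None else None
    )
    feats = riskmodel.assemble_features(cohort, betas=betas, submodel="ALL")
    y = cohort.labels
    seed = child_seed(cfg.seed, "train")
    gbdt = riskmodel.train_gbdt_cv(feats, y, k=cfg.k_folds, params=cfg.gbdt_params, seed=seed)
    logreg = riskmodel.train_logreg_cv(feats, y, l2_c=cfg.logreg_c, k=cfg.k_folds, seed=seed)
    scores = pd.DataFrame(
        {
            "sample_id": cohort.samples["sample_id"],
            "label": y,
            "gbdt_oof": gbdt.oof_scores,
            "logreg_oof": logreg.oof_scores,
        }
    )
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    eval_report = {
        "auc_gbdt": riskmodel.auc(gbdt.oof_scores, y),
        "auc_logreg": riskmodel.auc(logreg.oof_scores, y),
        "ap_gbdt": riskmodel.average_precision(gbdt.oof_scores, y),
        "ap_logreg": riskmodel.average_precision(logreg.oof_scores, y),
    }
    a, b, p = riskmodel.delong_test(gbdt.oof_scores, logreg.oof_scores, y)
    eval_report["delong_p_gbdt_vs_logreg"] = p
    with open(out / "eval.json", "w") as fh:
        json.dump(eval_report, fh, indent=1)
    table = riskmodel.youden_scale(gbdt.oof_scores, y)
    table.to_csv(out / "score_table.tsv", sep="\t", index=False)
    ctx.update(features=feats, gbdt=gbdt, logreg=logreg)
    return [out / "scores.tsv", out / "eval.json", out / "score_table.tsv"]


def _stage_interpret(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    feats, gbdt = ctx["features"], ctx["gbdt"]
    shap = interpret.compute_shap(gbdt, feats.X, groups=feats.groups)
    long = pd.DataFrame(shap.values, columns=shap.feature_names)
    long.insert(0, "sample_id", ctx["cohort"].samples["sample_id"].to_numpy())
    long.to_csv(out / "shap.tsv", sep="\t", index=False)
    tensor = interpret.compute_interactions(
        gbdt, feats.X, groups=feats.groups,
        max_individuals=cfg.max_interaction_individuals,
        seed=child_seed(cfg.seed, "interactions"),
    )
    inter = interpret.interaction_significance(tensor)
    inter.to_csv(out / "interactions.tsv", sep="\t", index=False)
    comp = interpret.complexity_scores(shap)
    comp.insert(0, "sample_id", ctx["cohort"].samples["sample_id"].to_numpy())
    comp.to_csv(out / "complexity.tsv", sep="\t", index=False)
    ctx.update(shap=shap, interactions=inter, complexity=comp)
    return [out / "shap.tsv", out / "interactions.tsv", out / "complexity.tsv"]


def _stage_subtype(cfg: PipelineConfig, out: Path, ctx: dict) -> list[Path]:
    cohort, shap = ctx["cohort"], ctx["shap"]
    cases = cohort.labels == 1
    emb = subtype.embed(
        shap.values[cases], n_pcs=cfg.n_pcs, k=cfg.knn_k,
        seed=child_seed(cfg.seed, "embed"),
    )
    ca = subtype.cluster(emb, resolution=cfg.resolution, seed=child_seed(cfg.seed, "leiden"))
    clusters = pd.DataFrame(
        {
            "sample_id": cohort.samples.loc[cases, "sample_id"].to_numpy(),
            "cluster": ca.labels,
        }
    )
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    report: dict = {"n_clusters": ca.n_clusters, "resolution": cfg.resolution}
    if ca.n_clusters > 1:
        onset = cohort.samples.loc[cases, "onset_age"].to_numpy(dtype=float)
        report["onset_logrank"] = subtype.onset_logrank(onset, ca.labels)
        report["complications"] = {}
        for comp in ("nephropathy", "neuropathy", "cvd", "retinopathy"):
            ev = cohort.samples.loc[cases, comp].to_numpy(dtype=int)
            report["complications"][comp] = {
                str(c): {
                    k: v
                    for k, v in subtype.complication_assoc(ev, ca.labels, c).items()
                    if k != "table"
                }
                for c in range(ca.n_clusters)
            }
    with open(out / "cluster_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    ctx["clusters"] = ca
    return [out / "clusters.tsv", out / "cluster_report.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "assoc": _stage_assoc,
    "finemap": _stage_finemap,
    "train": _stage_train,
    "interpret": _stage_interpret,
    "subtype": _stage_subtype,
}


def make_report(run_dir: str | Path) -> str:
    """Render a human-readable summary of a completed run directory."""
    run = Path(run_dir)
    lines = ["# Run report", ""]
    score_table = run / "score_table.tsv"
    if score_table.exists():
        df = pd.read_csv(score_table, sep="\t")
        lines.append("## Youden diagnostic scale")
        for _, r in df.iterrows():
            lines.append(
                f"  centile {r['case_centile']:>4.0f}: threshold {r['threshold']:.4f}, "
                f"sens {r['sensitivity_pct']:.2f}%, spec {r['specificity_pct']:.2f}%, "
                f"J {r['youden_j']:.4f}"
            )
        lines.append("")
    eval_json = run / "eval.json"
    if eval_json.exists():
        with open(eval_json) as fh:
            ev = json.load(fh)
        lines.append("## Model evaluation")
        for k, v in ev.items():
            lines.append(f"  {k}: {v:.6g}")
        lines.append("")
    inter = run / "interactions.tsv"
    if inter.exists():
        df = pd.read_csv(inter, sep="\t")
        sig = df[df["significant_q05"]] if "significant_q05" in df else df.iloc[:0]
        lines.append("## Significant interactions (q < 0.05)")
        if sig.empty:
            lines.append("  none significant")
        else:
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['feature_a']} x {r['feature_b']}: z={r['z']:.2f}, "
                    f"q={r['q']:.3g} [{r['category']}]"
                )
        lines.append("")
    creport = run / "cluster_report.json"
    if creport.exists():
        with open(creport) as fh:
            cr = json.load(fh)
        lines.append("## Genetic subtypes")
        lines.append(f"  clusters: {cr.get('n_clusters')}")
        if "onset_logrank" in cr:
            lr = cr["onset_logrank"]
            lines.append(
                f"  onset log-rank chi2 {lr['chi2']:.2f}, p {lr['p']:.3g}; "
                f"medians {lr['median_onset']}"
            )
        lines.append("")
    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
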