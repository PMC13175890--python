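"""End-to-end pipeline demo from a single config: simulate -> associate ->
fine-map -> train -> interpret -> subtype, with a manifest of output hashes
and a rendered report.

Outputs: results/pipeline_demo/ (cohort, summary stats, credible sets,
scores, interactions, clusters, manifest.json, report.md)
"""

from pathlib import Path

from t1grs_lab.pipeline import PipelineConfig, make_report, run_pipeline

if __name__ == "__main__":
    cfg = PipelineConfig.validated(
        {
            "n": 5000, "n_mhc": 12, "n_nonmhc": 48, "seed": 12345,
            "out_dir": "results/pipeline_demo",
            "max_interaction_individuals": 800, "n_perm": 200,
            "n_pcs": 50, "knn_k": 60,
        }
    )
    manifest = run_pipeline(cfg)
    for stage, info in manifest["stages"].items():
        print(f"{stage}: {info['seconds']}s, outputs {sorted(info['outputs'])}")
    print()
    print(make_report(cfg.out_dir))
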