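"""End-to-end evaluation: cohort synthesis to group classification.

Synthesizes a two-group cohort, extracts the 16 subject-level features
(whole-brain SC/NI in five bands from rest; N1/MMN amplitude/latency plus
ESC/ENI from the auditory task), runs group t-tests with FDR correction,
and evaluates four feature sets with a cross-validated RBF-SVM.
"""

from docndf import MFFSConfig, PipelineConfig, run_pipeline

config = PipelineConfig(n_per_group=8, rest_duration_s=24.0,
                        oddball=(20, 4, 3, 1000.0),
                        mffs=MFFSConfig(subpop_size=12, iterations=10,
                                        elite_count=2, cv_folds=4, seed=0))
report = run_pipeline(config, seed=5)

print("feature-set evaluations (stratified CV, pooled folds):")
for name, m in report["evaluations"].items():
    print(f"  {name:>8}: accuracy {m['accuracy']:.3f}  auc {m['auc']:.3f}  "
          f"f1 {m['f1']:.3f}")
print("MFFS-selected features:", ", ".join(
    report["mffs_selection"]["features"]))
sig = [r["channel"] for r in report["feature_stats"] if r["significant"]]
print("features significant after FDR:", ", ".join(sig) or "none")
# Accuracy near 1 reflects the deliberately large group contrasts of the
# synthetic cohort; the interesting outputs are which features separate the
# groups and that selection never underperforms the full set.
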