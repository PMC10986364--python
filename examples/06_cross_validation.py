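"""Run the whole pipeline under stratified 5-fold cross-validation and
compare the classifier with the KNN/SVM baselines on identical folds.

This is the programmatic form of `p3dseize cv --baselines`; with
repeats=5 it becomes the full five-times-repeated protocol.
"""

import p3dseize as pz

cfg = pz.PipelineConfig(
    synth=pz.SynthConfig(duration_s=1200.0, seizure_onsets_s=(1200.0,)),
    n_recordings=1,
    cv_k=5,
    cv_repeats=1,
    model=pz.ModelConfig.reduced(epochs=8),
    run_baselines=True,
    seed=7,
)
result = pz.run_pipeline(cfg)

print("retained features:",
      result.selection.ranked_names[: result.selection.chosen_k])
mean, std = result.report.mean, result.report.std
print("model (5-fold CV):")
for metric in ("accuracy", "sensitivity", "precision", "specificity"):
    print(f"  {metric:12s} {mean[metric]:.3f} ± {std[metric]:.3f}")
for name, rep in result.baseline_reports.items():
    print(f"{name.upper():4s} mean accuracy: {rep.mean['accuracy']:.3f}")
print("All methods share one fold plan (digest "
      f"{result.report.plan_digest}), so the comparison is paired.")
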