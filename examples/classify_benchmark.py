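"""Full pipeline benchmark: simulate, extract features, cross-validate.

Runs the default study conditions (100 images per class at 128x128,
stratified 5-fold CV of the logistic classifier) and prints the pooled
confusion counts and metrics.
"""

from ovatex import pipeline, synth

result = pipeline.run_benchmark(
    synth.SyntheticConfig(n_per_class=100, image_size=(128, 128), seed=7),
    pipeline.PipelineConfig(cv_folds=5, seed=7),
)

c = result.cv.pooled_counts
m = result.cv.pooled_metrics
print(f"pooled confusion counts: tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn}")
print(f"accuracy  {m.accuracy:.3f}")
print(f"precision {m.precision:.3f}")
print(f"recall    {m.recall:.3f}")
print(f"f1        {m.f1:.3f}")
print("per-fold accuracy:", [round(f.accuracy, 3) for f in result.cv.fold_metrics])
# accuracy = (tp+tn)/total, the fraction of images whose benign/malignant
# label the cross-validated classifier reproduces.
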