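"""Train both branches on a small synthetic dataset and fuse their scores.

Uses the 'smoke' preset with a handful of epochs so the whole script runs in
about a minute; prints per-branch validation accuracy, the fusion weight
selected on the validation subset, and held-out test metrics.
"""

import numpy as np

from moafuse.fp_cs import FPBranchConfig
from moafuse.synthetic import PRESETS, SynthConfig, generate_dataset
from moafuse.train_eval import (
    TrainConfig,
    compute_metrics,
    fuse_scores,
    predict_branch,
    stratified_split,
    train_branch,
)

dataset, _ = generate_dataset(SynthConfig(seed=0, **PRESETS["smoke"]))
labels = dataset.labels_by_compound()
recs = [type("R", (), {"compound_id": c, "moa_label": l})() for c, l in labels.items()]
plan = stratified_split(recs, k=10, seed=0)
train_ids = plan.ids_in(plan.folds[0][0])
val_ids = plan.ids_in(plan.folds[0][1])
test_ids = plan.ids_in(plan.test_subset)
val_ds, test_ds = dataset.subset(val_ids), dataset.subset(test_ids)
y_val = np.array([s.moa_label for s in val_ds.samples])
y_test = np.array([s.moa_label for s in test_ds.samples])

fp_cfg = FPBranchConfig(d=128, d_c=128, d_s=128, d_f=32, fpc_hidden=256, fps_hidden=128)
res_ci = train_branch(dataset, "ci", TrainConfig(epochs=6, lr_ci=1e-3, seed=0), train_ids, val_ids)
res_fp = train_branch(dataset, "fp", TrainConfig(epochs=10, lr_fp=1e-3, seed=0),
                      train_ids, val_ids, fp_config=fp_cfg)
print(f"image branch final val accuracy:       {res_ci.history[-1]['val_accuracy']:.3f}")
print(f"fingerprint branch final val accuracy: {res_fp.history[-1]['val_accuracy']:.3f}")

val_ci, val_fp = predict_branch(res_ci, val_ds), predict_branch(res_fp, val_ds)
betas = [round(b, 1) for b in np.arange(0, 1.01, 0.1)]
beta = max(betas, key=lambda b: (fuse_scores(val_ci, val_fp, b).argmax(1) == y_val).mean())
print(f"selected fusion weight beta = {beta}")

fused = fuse_scores(predict_branch(res_ci, test_ds), predict_branch(res_fp, test_ds), beta)
m = compute_metrics(y_test, fused.argmax(axis=1), dataset.n_classes)
print(f"held-out test: accuracy={m.accuracy:.3f}  macro-F1={m.macro_f1:.3f}  "
      f"weighted-F1={m.weighted_f1:.3f}")
# The fused score is beta*score_CI + (1-beta)*score_FP per sample; on this
# easy smoke dataset both branches are strong, so fusion matches the best.
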