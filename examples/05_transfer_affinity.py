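"""Transfer learning: from abundant binding data to scarce affinity labels.

Pretrains a 1-D CNN on binding-vs-random discrimination, freezes its first
three conv layers, fine-tunes the rest on a 72-sequence affinity dataset
(20 high / 52 low at the 90-s threshold) under 4-fold CV, and runs the
composition-preserving shuffling ablation.
"""

import numpy as np

from cntbind import kinetics, library, synthetic
from cntbind.ml import (
    ModelSpec,
    make_binding_dataset,
    make_encoded_dataset,
    shuffled_evaluation,
    train_eval_binding,
    transfer_affinity,
)

model = synthetic.ac_favoring_model(strength=0.12)
rounds = synthetic.simulate_selection(
    model, n_unique=50000, n_rounds=6, n_draw=50000, pcr_cv=0.2, seed=11
)

# pretrain the CNN on binding vs random
seqs, labels, _ = make_binding_dataset(rounds[6], n_pos=1500, n_neg=1500, seed=33)
ds = make_encoded_dataset(seqs, labels, mode="onehot")
spec = ModelSpec(
    "cnn",
    {"n_conv": 5, "filters": 16, "kernel": 5, "fc": 32,
     "max_epochs": 30, "patience": 6},
)
report, models = train_eval_binding(ds, spec, repeats=1, seed=4, return_models=True)
print(f"binding CNN test AUC: {report.mean('auc'):.3f}")

# synthetic 72-sequence affinity table with the measured-style composition
ranked = [s for s, _ in library.rank_unique(rounds[6].records)]
rng = np.random.default_rng(5)
lut = np.array(list("ACGT"))
random36 = ["".join(row) for row in lut[rng.integers(0, 4, size=(36, 30))]]
table = synthetic.simulate_affinity_table(model, ranked[:36] + random36, seed=6, n_high=20)
labelled = kinetics.label_affinity_table(table, threshold_s=90.0)
n_high = int((labelled["label"] == "high").sum())
print(f"affinity dataset: {n_high} high / {72 - n_high} low at the 90-s threshold")

aff = make_encoded_dataset(
    list(labelled["sequence"]),
    (labelled["label"] == "high").astype(int).to_numpy(),
    mode="onehot",
)
arep, oof = transfer_affinity(
    models[0], aff, n_freeze=3, folds=4, repeats=3, seed=7, fine_tune_epochs=40
)
print(
    f"transfer-learned affinity AUC (pooled out-of-fold, 3 repeats): "
    f"{arep.mean('auc'):.3f} +/- {arep.sd('auc'):.3f}"
)

# shuffling ablation on an order-dependent ground truth
mseqs, my = synthetic.generate_motif_dataset(1500, seed=9)
_, mmodels = train_eval_binding(
    make_encoded_dataset(mseqs, my, mode="onehot"),
    ModelSpec("cnn", {"n_conv": 3, "filters": 16, "kernel": 5, "fc": 32,
                      "max_epochs": 40, "patience": 8}),
    repeats=1, seed=10, return_models=True,
)
ts, ty = synthetic.generate_motif_dataset(500, seed=12)
res = shuffled_evaluation(mmodels[0], ts, ty, n_shuffles=5, seed=13)
print(
    f"shuffling ablation (motif ground truth): original AUC "
    f"{res['original']['auc']:.3f}, shuffled {res['shuffled_auc_mean']:.3f}, "
    f"drop {res['auc_drop']:.3f} (p = {res['p_value']:.3f})"
)
print(
    "\nThe frozen conv layers carry the binding features to the scarce\n"
    "affinity task; the AUC drop under composition-preserving shuffles\n"
    "shows the model reads base order, not just base composition."
)
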