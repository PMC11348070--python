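"""Binding prediction: top-ranked library sequences vs random 30-mers.

Evolves a library for six rounds, builds a balanced binding dataset
(top-ranked positives, random negatives), and evaluates a random-forest
classifier on 2-mer features under repeated 60/20/20 splits.
"""

from cntbind import synthetic
from cntbind.ml import (
    ModelSpec,
    make_binding_dataset,
    make_encoded_dataset,
    train_eval_binding,
)

model = synthetic.ac_favoring_model(strength=0.1, temperature=2.0)
rounds = synthetic.simulate_selection(
    model, n_unique=30000, n_rounds=6, n_draw=30000, pcr_cv=0.2, seed=4
)

print("binding-prediction AUC by round (RF, 2-mer features):")
for r in (3, 4, 5, 6):
    seqs, labels, _ = make_binding_dataset(rounds[r], n_pos=1000, n_neg=1000, seed=r)
    ds = make_encoded_dataset(seqs, labels, mode="kmer", k=2)
    report = train_eval_binding(
        ds, ModelSpec("rf", {"n_estimators": 150}), repeats=3, seed=5
    )
    print(f"  round {r}: AUC = {report.mean('auc'):.3f} +/- {report.sd('auc'):.3f}")

print(
    "\nAUC rises with the round: selection concentrates the sequence\n"
    "signature that separates enriched binders from random sequences."
)
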