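"""Binding and affinity classifiers with the repeated-split protocol.

Five model families: random forest (RF, scikit-learn) and four neural
families (MLP, CNN, GRU, transformer) on the in-package numpy engine.
RF and MLP consume k-mer features (2-mer default); CNN/GRU/transformer
consume 30x4 one-hot input.

Protocols implemented:

* ``train_eval_binding`` — repeated random 60/20/20 splits, validation-AUC
  early stopping for the neural families, five metrics averaged over
  repeats (binding vs random discrimination);
* ``transfer_affinity`` — transfer learning from the binding CNN to the
  scarce affinity task: first *n_freeze* conv layers frozen, remaining
  layers fine-tuned under repeated stratified k-fold CV with pooled
  out-of-fold probabilities;
* ``shuffled_evaluation`` — composition-preserving per-sequence shuffles of
  the test set, quantifying how much of the model's signal is base order
  rather than base composition;
* ``predict_rank`` — scoring of candidate pools and extraction of top /
  bottom sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ..library import rank_unique, top_n
from ..sequences import ALPHABET, INSERT_LENGTH
from .encoding import (
    EncodedDataset,
    make_encoded_dataset,
    shuffle_preserving_composition,
)
from .metrics import EvalReport, compute_metrics
from .nn import CNNNet, NeuralNetClassifier, build_gru, build_mlp, build_transformer

FAMILIES = ("rf", "mlp", "cnn", "gru", "transformer")

# repository-default architectures (overridable via ModelSpec.hyperparams)
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500},
    "mlp": {"hidden": (128, 64)},
    "cnn": {"n_conv": 5, "filters": 64, "kernel": 5, "fc": 64},
    "gru": {"hidden": 64},
    "transformer": {"d": 64, "n_heads": 4, "n_blocks": 2},
}
DEFAULT_TRAINING = {"lr": 1e-3, "batch_size": 64, "max_epochs": 200, "patience": 10}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        known = set(DEFAULT_HYPERPARAMS[self.family]) | set(DEFAULT_TRAINING)
        unknown = set(self.hyperparams) - known
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.family}: {sorted(unknown)}")

    def resolved(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMS[self.family])
        hp.update(dict(DEFAULT_TRAINING))
        hp.update(self.hyperparams)
        return hp

    @property
    def encoding_mode(self) -> str:
        return "kmer" if self.family in ("rf", "mlp") else "onehot"


class RFModel:
    """Thin wrapper giving the RF the same fit/predict surface as the nets."""

    def __init__(self, spec: ModelSpec, seed: int):
        hp = spec.resolved()
        self.clf = RandomForestClassifier(
            n_estimators=hp["n_estimators"], random_state=seed, n_jobs=1
        )

    def fit(self, X, y, X_val=None, y_val=None):
        self.clf.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.clf.predict_proba(X)[:, 1]


def build_model(spec: ModelSpec, seed: int | None = None, d_in: int | None = None):
    """Instantiate a classifier for *spec*; *seed* overrides spec.seed."""
    seed = spec.seed if seed is None else seed
    hp = spec.resolved()
    if spec.family == "rf":
        return RFModel(spec, seed)
    rng = np.random.default_rng(seed)
    if spec.family == "mlp":
        if d_in is None:
            raise ValueError("mlp requires d_in (k-mer feature dimension)")
        net = build_mlp(d_in, tuple(hp["hidden"]), rng)
    elif spec.family == "cnn":
        net = CNNNet(hp["n_conv"], hp["filters"], hp["kernel"], hp["fc"], rng)
    elif spec.family == "gru":
        net = build_gru(hp["hidden"], rng)
    else:
        net = build_transformer(
            hp["d"], hp["n_heads"], hp["n_blocks"], INSERT_LENGTH, rng
        )
    return NeuralNetClassifier(
        net,
        seed=seed,
        lr=hp["lr"],
        batch_size=hp["batch_size"],
        max_epochs=hp["max_epochs"],
        patience=hp["patience"],
    )


def _flatten_for(spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    # tabular families see k-mer vectors; sequence families see (n, 30, 4)
    if spec.family in ("rf", "mlp") and X.ndim != 2:
        raise ValueError(f"{spec.family} expects 2-D k-mer features")
    if spec.family in ("cnn", "gru", "transformer") and X.ndim != 3:
        raise ValueError(f"{spec.family} expects (n, 30, 4) one-hot features")
    return X


def make_binding_dataset(
    round_lib,
    n_pos: int = 10000,
    n_neg: int = 10000,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Positives: the top-*n_pos* ranked library sequences; negatives:
    uniform random 30-mers rejection-sampled against the positive set.

    Returns (sequences, labels, ids).
    """
    ranked = rank_unique(round_lib.records)
    if len(ranked) < n_pos:
        raise ValueError(
            f"library has {len(ranked)} unique sequences, need {n_pos} positives"
        )
    positives = [s for s, _ in top_n(ranked, n_pos)]
    pos_set = set(positives)
    rng = np.random.default_rng(seed)
    negatives: list[str] = []
    lut = np.array(list(ALPHABET))
    while len(negatives) < n_neg:
        draw = rng.integers(0, 4, size=(n_neg - len(negatives), INSERT_LENGTH))
        for row in lut[draw]:
            s = "".join(row)
            if s not in pos_set:
                negatives.append(s)
    sequences = positives + negatives
    labels = np.array([1] * n_pos + [0] * n_neg)
    ids = [f"pos{i}" for i in range(n_pos)] + [f"neg{i}" for i in range(n_neg)]
    return sequences, labels, ids


def _three_way_split(
    rng: np.random.Generator,
    labels: np.ndarray,
    split: tuple[float, float, float],
    max_resample: int = 20,
):
    n = len(labels)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    for _ in range(max_resample):
        perm = rng.permutation(n)
        tr, va, te = perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]
        if all(len(np.unique(labels[part])) == 2 for part in (tr, va, te) if len(part)):
            return tr, va, te
    raise RuntimeError("could not draw a split containing both classes")


def train_eval_binding(
    dataset: EncodedDataset,
    spec: ModelSpec,
    split: tuple[float, float, float] = (0.60, 0.20, 0.20),
    repeats: int = 10,
    seed: int = 0,
    return_models: bool = False,
):
    """Repeated random-split train/validate/test evaluation.

    Each repeat draws a fresh 60/20/20 split, fits the model on the training
    part (neural families early-stop on validation AUC) and scores the five
    metrics on the held-out test part.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    X = _flatten_for(spec, dataset.features)
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("binding dataset must contain both classes")
    report = EvalReport()
    models = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        tr, va, te = _three_way_split(rng, y, split)
        model = build_model(spec, seed=seed + 10_000 + rep, d_in=X.shape[-1])
        model.fit(X[tr], y[tr], X[va], y[va])
        report.add(compute_metrics(y[te], model.predict_proba(X[te])))
        if return_models:
            models.append(model)
    return (report, models) if return_models else report


def transfer_affinity(
    base_model: NeuralNetClassifier,
    affinity_data: EncodedDataset,
    n_freeze: int = 3,
    folds: int = 4,
    repeats: int = 10,
    seed: int = 0,
    fine_tune_epochs: int = 60,
    lr: float = 1e-3,
) -> tuple[EvalReport, np.ndarray]:
    """Fine-tune the binding CNN on the scarce affinity dataset.

    Per repeat: stratified *folds*-fold CV; in every fold the base network
    is copied, its first *n_freeze* conv layers frozen, and the remaining
    layers fine-tuned on the training folds; out-of-fold probabilities are
    pooled over all sequences.  Frozen parameters are asserted bit-identical
    after fine-tuning.

    Returns the per-repeat report and the (repeats, n_sequences) matrix of
    out-of-fold probabilities.
    """
    if not isinstance(base_model.net, CNNNet):
        raise TypeError("transfer_affinity requires a CNN base model")
    X = affinity_data.features
    y = affinity_data.labels
    if X.ndim != 3:
        raise ValueError("affinity dataset must be one-hot encoded")
    report = EvalReport()
    oof = np.zeros((repeats, len(y)))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        probs = np.zeros(len(y))
        for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("stratification failed: single-class training fold")
            model = base_model.clone()
            model.seed = seed + 100 * rep + fold_idx
            model.lr = lr
            model.max_epochs = fine_tune_epochs
            model.patience = fine_tune_epochs  # fixed-epoch fine-tuning
            net: CNNNet = model.net  # type: ignore[assignment]
            for p in net.params():
                p.trainable = True
            net.freeze_conv(n_freeze)
            frozen_before = net.frozen_param_values(n_freeze)
            model.fit(X[tr], y[tr])
            frozen_after = net.frozen_param_values(n_freeze)
            for before, after in zip(frozen_before, frozen_after):
                if not np.array_equal(before, after):
                    raise AssertionError("frozen conv parameters changed during fine-tuning")
            probs[te] = model.predict_proba(X[te])
        oof[rep] = probs
        report.add(compute_metrics(y, probs))
    return report, oof


def predict_rank(
    model,
    candidate_seqs: Sequence[str],
    n_top: int = 5,
    n_bottom: int = 5,
    encoding_mode: str = "onehot",
    k: int = 2,
) -> tuple[list[str], list[str]]:
    """Score candidates; return the top and bottom sequences by probability.

    Ties are broken lexicographically so the extraction is deterministic.
    """
    ds = make_encoded_dataset(
        candidate_seqs, np.zeros(len(candidate_seqs)), mode=encoding_mode, k=k
    )
    probs = model.predict_proba(ds.features)
    order_desc = sorted(range(len(probs)), key=lambda i: (-probs[i], candidate_seqs[i]))
    order_asc = sorted(range(len(probs)), key=lambda i: (probs[i], candidate_seqs[i]))
    top = [candidate_seqs[i] for i in order_desc[:n_top]]
    bottom = [candidate_seqs[i] for i in order_asc[:n_bottom]]
    return top, bottom


def shuffled_evaluation(
    model,
    test_seqs: Sequence[str],
    test_labels: Sequence[int],
    encoding_mode: str = "onehot",
    k: int = 2,
    n_shuffles: int = 1,
    seed: int = 0,
) -> dict:
    """Compare performance on original vs composition-preserving shuffles.

    Each shuffle permutes the bases within every test sequence (its 1-mer
    profile is unchanged), so any performance drop isolates the model's use
    of base order.  The p-value is a randomization test: the fraction of
    shuffles whose AUC is at least the original's.
    """
    y = np.asarray(test_labels, dtype=int)
    ds = make_encoded_dataset(test_seqs, y, mode=encoding_mode, k=k)
    original = compute_metrics(y, model.predict_proba(ds.features))
    rng = np.random.default_rng(seed)
    shuffled_metrics = []
    for _ in range(n_shuffles):
        shuf = [shuffle_preserving_composition(s, rng) for s in test_seqs]
        ds_s = make_encoded_dataset(shuf, y, mode=encoding_mode, k=k)
        shuffled_metrics.append(compute_metrics(y, model.predict_proba(ds_s.features)))
    shuf_aucs = np.array([m["auc"] for m in shuffled_metrics])
    p_value = (1 + int(np.sum(shuf_aucs >= original["auc"]))) / (n_shuffles + 1)
    return {
        "original": original,
        "shuffled": shuffled_metrics,
        "shuffled_auc_mean": float(shuf_aucs.mean()),
        "auc_drop": float(original["auc"] - shuf_aucs.mean()),
        "p_value": float(p_value),
    }
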