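"""Encodings, metrics and the binding/affinity evaluation protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cntbind import synthetic as syn
from cntbind.ml import (
    ModelSpec,
    build_model,
    compute_metrics,
    decode_onehot,
    encode_kmer,
    encode_onehot,
    make_binding_dataset,
    make_encoded_dataset,
    predict_rank,
    rank_auc,
    shuffle_preserving_composition,
    shuffled_evaluation,
    train_eval_binding,
    transfer_affinity,
)
from conftest import random_inserts

seq_strategy = st.text(alphabet="ACGT", min_size=30, max_size=30)


class TestKmerEncoding:
    def test_homopolymer_monomer_counts(self):
        X = encode_kmer(["A" * 30], k=1)
        np.testing.assert_array_equal(X[0], [30, 0, 0, 0])

    def test_alternating_dimer_counts(self):
        X = encode_kmer(["AC" * 15], k=2)
        kmer_idx = {m: i for i, m in enumerate(_kmers(2))}
        assert X[0, kmer_idx["AC"]] == 15
        assert X[0, kmer_idx["CA"]] == 14
        assert X[0].sum() == 29

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_row_sums(self, k):
        X = encode_kmer(random_inserts(10, seed=1), k=k)
        np.testing.assert_array_equal(X.sum(axis=1), np.full(10, 31 - k))
        Xn = encode_kmer(random_inserts(10, seed=1), k=k, normalize=True)
        np.testing.assert_allclose(Xn.sum(axis=1), 1.0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            encode_kmer(["A" * 30], k=6)


def _kmers(k):
    from cntbind.library import all_kmers

    return all_kmers(k)


class TestOneHotEncoding:
    def test_homopolymer_column(self):
        M = encode_onehot("A" * 30)
        assert M.shape == (30, 4)
        np.testing.assert_array_equal(M[:, 0], 1.0)
        assert M.sum() == 30

    def test_rows_sum_to_one(self):
        X = encode_onehot(random_inserts(5, seed=2))
        np.testing.assert_array_equal(X.sum(axis=2), np.ones((5, 30)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq_strategy)
    def test_argmax_decoding_round_trip(self, seq):
        assert decode_onehot(encode_onehot(seq)) == seq

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq_strategy, st.integers(0, 2**31 - 1))
    def test_shuffle_preserves_column_sums(self, seq, seed):
        rng = np.random.default_rng(seed)
        shuffled = shuffle_preserving_composition(seq, rng)
        assert sorted(shuffled) == sorted(seq)
        np.testing.assert_array_equal(
            encode_onehot(seq).sum(axis=0), encode_onehot(shuffled).sum(axis=0)
        )


class TestMetrics:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert rank_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert rank_auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_enumerated_pair_concordance(self):
        # labels (1,1,0,0), scores (0.9,0.4,0.6,0.1): 3 of 4 pairs concordant
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.1])
        assert rank_auc(y, s) == 0.75

    def test_rank_auc_equals_trapezoidal_roc_area(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(10, 60)
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = rng.random(n)
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_undefined(self):
        from cntbind.ml.metrics import MetricError

        with pytest.raises(MetricError):
            rank_auc(np.ones(5), np.random.default_rng(0).random(5))

    def test_threshold_metrics(self):
        m = compute_metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.6, 0.7, 0.1]))
        assert m["accuracy"] == 0.75
        assert m["recall"] == 1.0
        assert m["precision"] == pytest.approx(2 / 3)
        fpr, tpr = m["roc"]
        assert fpr[0] == 0.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestBindingDataset:
    def test_negatives_disjoint_balanced_deterministic(self, small_selection):
        seqs, y, ids = make_binding_dataset(small_selection[0], 10, 10, seed=5)
        assert len(seqs) == 20 and y.sum() == 10
        assert set(seqs[:10]).isdisjoint(seqs[10:])
        seqs2, y2, _ = make_binding_dataset(small_selection[0], 10, 10, seed=5)
        assert seqs == seqs2

    def test_too_small_library_rejected(self, small_selection):
        with pytest.raises(ValueError):
            make_binding_dataset(small_selection[6], n_pos=10**6, n_neg=10)


class TestTrainEval:
    def test_rf_is_deterministic_and_learns_separable_rule(self):
        seqs = random_inserts(400, seed=6)
        y = np.array([1 if s.count("A") + s.count("C") > 15 else 0 for s in seqs])
        ds = make_encoded_dataset(seqs, y, mode="kmer", k=2)
        spec = ModelSpec("rf", {"n_estimators": 100})
        r1 = train_eval_binding(ds, spec, repeats=2, seed=1)
        r2 = train_eval_binding(ds, spec, repeats=2, seed=1)
        assert r1.per_repeat == r2.per_repeat
        assert r1.mean("auc") > 0.9

    def test_invalid_split(self):
        ds = make_encoded_dataset(random_inserts(20, seed=7), [0, 1] * 10, "kmer")
        with pytest.raises(ValueError):
            train_eval_binding(ds, ModelSpec("rf"), split=(0.5, 0.2, 0.2))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("svm")
        with pytest.raises(ValueError):
            ModelSpec("cnn", {"bogus": 1})


class TestPredictRank:
    def test_tie_break_lexicographic(self):
        class Flat:
            def predict_proba(self, X):
                return np.full(len(X), 0.5)

        seqs = sorted(random_inserts(8, seed=8))
        top, bottom = predict_rank(Flat(), seqs, n_top=3, n_bottom=3)
        assert top == seqs[:3]
        assert bottom == seqs[:3]  # same order on flat scores

    def test_top_bottom_disjoint_for_real_model(self):
        seqs, y = syn.generate_motif_dataset(120, seed=9)
        ds = make_encoded_dataset(seqs, y, mode="kmer", k=1)
        model = build_model(ModelSpec("rf", {"n_estimators": 50}), seed=1)
        model.fit(ds.features, ds.labels)
        top, bottom = predict_rank(
            model, seqs, n_top=5, n_bottom=5, encoding_mode="kmer", k=1
        )
        assert set(top).isdisjoint(bottom)


@pytest.fixture(scope="module")
def pretrained_cnn():
    seqs, y = syn.generate_motif_dataset(600, seed=10)
    ds = make_encoded_dataset(seqs, y, mode="onehot")
    spec = ModelSpec(
        "cnn",
        {"n_conv": 5, "filters": 8, "kernel": 3, "fc": 16,
         "max_epochs": 10, "patience": 10},
    )
    _, models = train_eval_binding(ds, spec, repeats=1, seed=2, return_models=True)
    return models[0]


class TestTransfer:
    def make_affinity(self, n=72, seed=11):
        seqs, y = syn.generate_motif_dataset(n, seed=seed)
        return make_encoded_dataset(seqs, y, mode="onehot")

    def test_frozen_layers_bit_identical(self, pretrained_cnn):
        aff = self.make_affinity()
        before = pretrained_cnn.net.frozen_param_values(3)
        report, oof = transfer_affinity(
            pretrained_cnn, aff, n_freeze=3, folds=4, repeats=2, seed=3,
            fine_tune_epochs=5,
        )
        after = pretrained_cnn.net.frozen_param_values(3)
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        assert oof.shape == (2, 72)
        assert len(report) == 2

    def test_full_freeze_updates_only_head(self, pretrained_cnn):
        aff = self.make_affinity(seed=12)
        base_state = pretrained_cnn.get_state()
        report, _ = transfer_affinity(
            pretrained_cnn, aff, n_freeze=5, folds=4, repeats=1, seed=4,
            fine_tune_epochs=5,
        )
        # the base model itself is never mutated
        for p, v in zip(pretrained_cnn.net.params(), base_state):
            np.testing.assert_array_equal(p.value, v)

    def test_requires_cnn_base(self):
        from cntbind.ml.nn import NeuralNetClassifier, build_gru

        rng_model = NeuralNetClassifier(build_gru(4, np.random.default_rng(0)))
        with pytest.raises(TypeError):
            transfer_affinity(rng_model, self.make_affinity(), repeats=1)


class TestShuffledEvaluation:
    def test_shuffled_sequences_keep_composition(self):
        seqs, y = syn.generate_motif_dataset(40, seed=13)

        class Flat:
            def predict_proba(self, X):
                return np.linspace(0, 1, len(X))

        res = shuffled_evaluation(Flat(), seqs, y, n_shuffles=2, seed=14)
        assert set(res) >= {"original", "shuffled", "auc_drop", "p_value"}
        assert 0 < res["p_value"] <= 1
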