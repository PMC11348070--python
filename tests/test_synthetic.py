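"""Generator behaviour: scoring, selection, traces, toy trajectories."""

import itertools

import numpy as np
import pytest

from cntbind import synthetic as syn
from cntbind import trajectory as trj
from cntbind.sequences import SequenceError


class TestScoreSequence:
    def test_zero_weights_score_zero(self):
        model = syn.AffinityModel()
        assert syn.score_sequence(model, "ACGT" * 7 + "AC") == 0.0

    def test_base_weights_additive(self):
        model = syn.AffinityModel(base_weights={"A": 1.0})
        assert syn.score_sequence(model, "A" * 30) == 30.0
        assert syn.score_sequence(model, "A" * 15 + "C" * 15) == 15.0

    def test_dimer_weights_overlapping(self):
        model = syn.AffinityModel(dimer_weights={"AC": 1.0})
        # (AC)x15 contains 15 overlapping AC dimers
        assert syn.score_sequence(model, "AC" * 15) == 15.0

    def test_motif_term_is_order_dependent(self):
        """Brute force over all distinct permutations of a 6-nt prefix: a
        position-anchored motif scores differently across composition-
        preserving rearrangements."""
        model = syn.AffinityModel(motif_weights=((0, "ACG", 2.0),))
        pad = "T" * 24
        scores = {}
        for perm in set(itertools.permutations("ACGTTT")):
            seq = "".join(perm) + pad
            scores[seq] = syn.score_sequence(model, seq)
        values = set(scores.values())
        assert values == {0.0, 2.0}
        assert scores["ACGTTT" + pad] == 2.0
        assert scores["CAGTTT" + pad] == 0.0

    def test_invalid_sequence_rejected(self):
        model = syn.AffinityModel()
        with pytest.raises(SequenceError):
            syn.score_sequence(model, "A" * 29)

    def test_model_validation(self):
        with pytest.raises(syn.GeneratorError):
            syn.AffinityModel(temperature=0.0)
        with pytest.raises(syn.GeneratorError):
            syn.AffinityModel(motif_weights=((28, "ACG", 1.0),))


class TestInitialLibrary:
    def test_deterministic_under_seed(self):
        a = syn.generate_initial_library(1000, seed=7)
        b = syn.generate_initial_library(1000, seed=7)
        assert [(r.sequence, r.count) for r in a.records] == [
            (r.sequence, r.count) for r in b.records
        ]

    def test_uniform_base_composition(self):
        lib = syn.generate_initial_library(4000, seed=1)
        chars = "".join(r.sequence for r in lib.records)
        n = len(chars)
        se = np.sqrt(0.25 * 0.75 / n)
        for b in "ACGT":
            assert abs(chars.count(b) / n - 0.25) < 3 * se

    def test_single_record(self):
        lib = syn.generate_initial_library(1, seed=3)
        assert len(lib.records) == 1
        assert lib.records[0].count == 1
        assert lib.round_index == 0

    def test_invalid_inputs(self):
        with pytest.raises(syn.GeneratorError):
            syn.generate_initial_library(0)
        with pytest.raises(syn.GeneratorError):
            syn.generate_initial_library(5, counts_dist="zipf")


class TestSelectionRound:
    def test_high_temperature_limit_is_plain_resampling(self, ac_model):
        lib = syn.generate_initial_library(2000, seed=5)
        soft = syn.AffinityModel(
            base_weights=ac_model.base_weights, temperature=1e9
        )
        n_draw = 20000
        nxt = syn.simulate_selection_round(lib, soft, n_draw=n_draw, seed=6)
        # count-weighted composition matches a plain multinomial resample of
        # the previous round: compare to the prev library's own composition
        # with the sequence-level resampling standard error
        for b in "ACGT":
            prev_frac = np.array([r.sequence.count(b) / 30 for r in lib.records])
            mu, sd = prev_frac.mean(), prev_frac.std()
            got = sum(r.sequence.count(b) / 30 * r.count for r in nxt.records) / n_draw
            assert abs(got - mu) < 3 * sd / np.sqrt(n_draw) + 1e-12

    def test_two_sequence_boltzmann_probability(self):
        # scores 0 and 10 at temperature 1: the strong binder should take
        # essentially every draw (e^10/(1+e^10) ~ 0.99995)
        from cntbind.sequences import SequenceRecord

        model = syn.AffinityModel(base_weights={"A": 10.0 / 30.0}, temperature=1.0)
        prev = syn.LibraryRound(
            round_index=0,
            records=[SequenceRecord("A" * 30, 1), SequenceRecord("C" * 30, 1)],
            seed=0,
        )
        nxt = syn.simulate_selection_round(prev, model, n_draw=10000, seed=1)
        counts = {r.sequence: r.count for r in nxt.records}
        p = np.exp(10) / (1 + np.exp(10))
        frac = counts.get("A" * 30, 0) / 10000
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10000) + 1e-12

    def test_zero_pcr_noise_counts_are_multinomial(self, ac_model):
        lib = syn.generate_initial_library(100, seed=2)
        nxt = syn.simulate_selection_round(lib, ac_model, n_draw=500, pcr_cv=0.0, seed=3)
        assert nxt.total_count() == 500
        assert nxt.round_index == 1

    def test_empty_previous_round_rejected(self, ac_model):
        with pytest.raises(syn.GeneratorError):
            syn.simulate_selection_round(
                syn.LibraryRound(0, [], 0), ac_model, n_draw=10
            )

    def test_selection_enriches_favoured_bases(self, small_selection):
        from cntbind.library import enrichment_table

        table = enrichment_table(small_selection, k=1, n_top=2000)
        ac = [table.frequency(r, "AC") for r in range(7)]
        assert ac[6] > ac[0] + 0.05


class TestKineticTraceGenerator:
    def test_value_at_addition_time(self):
        tr = syn.simulate_kinetic_trace(100.0, 1129.0, 1115.0, noise_sd_nm=0.0)
        i = np.searchsorted(tr.times, tr.t_add)
        assert tr.wavelengths[i] == pytest.approx(1129.0)

    def test_one_time_constant_later(self):
        tr = syn.simulate_kinetic_trace(
            100.0, 1129.0, 1115.0, dt_s=10.0, total_s=600.0, t_add_s=100.0
        )
        i = np.searchsorted(tr.times, 200.0)  # t - t_add = tau
        assert tr.wavelengths[i] == pytest.approx(1115.0 + 14.0 / np.e)

    def test_evaluation_at_three_time_constants(self):
        # 1115 + 14 e^-3 = 1115.6969..., from direct evaluation of the decay
        tr = syn.simulate_kinetic_trace(
            100.0, 1129.0, 1115.0, dt_s=20.0, total_s=600.0, t_add_s=100.0
        )
        i = np.searchsorted(tr.times, 400.0)
        assert tr.wavelengths[i] == pytest.approx(1115.0 + 14.0 * np.exp(-3.0))

    def test_censored_trace_is_flat(self):
        tr = syn.simulate_kinetic_trace(None, noise_sd_nm=0.0)
        assert np.all(tr.wavelengths == 1129.0)

    def test_invalid_tau(self):
        with pytest.raises(syn.GeneratorError):
            syn.simulate_kinetic_trace(-5.0)

    def test_tsv_round_trip(self, tmp_path):
        tr = syn.simulate_kinetic_trace(50.0, noise_sd_nm=0.2, seed=9)
        p = tmp_path / "trace.tsv"
        tr.to_tsv(p)
        back = syn.KineticTrace.from_tsv(p)
        np.testing.assert_allclose(back.times, tr.times)
        np.testing.assert_allclose(back.wavelengths, tr.wavelengths)
        assert back.t_add == tr.t_add


class TestToyTrajectory:
    def test_cnt_beads_on_stated_radius(self):
        t = syn.simulate_toy_trajectory(n_frames=2, wobble_sd_nm=0.0, seed=0)
        cnt = t.positions[0][t.role_mask(["cnt"])]
        radial = np.linalg.norm(cnt[:, :2], axis=1)
        assert np.all(np.abs(radial - 0.6) < 1e-9)

    def test_planted_near_pair_recovered_every_frame(self):
        t = syn.simulate_toy_trajectory(
            n_frames=4, planted_pairs=[(5, 12, 0.4)], wobble_sd_nm=0.0, seed=0
        )
        for f in range(4):
            pairs = trj.detect_hbonds(t, f)
            assert pairs == [(5, 12)]
            assert trj.classify_near_far(pairs, t, f) == ["near"]

    def test_planted_far_pair(self):
        t = syn.simulate_toy_trajectory(
            n_frames=2, planted_pairs=[(5, 12, 0.7)], wobble_sd_nm=0.0, seed=0
        )
        pairs = trj.detect_hbonds(t, 0)
        assert pairs == [(5, 12)]
        assert trj.classify_near_far(pairs, t, 0) == ["far"]

    def test_overlapping_planted_pairs_rejected(self):
        with pytest.raises(syn.GeneratorError):
            syn.simulate_toy_trajectory(
                n_frames=1, planted_pairs=[(5, 12, 0.4), (12, 20, 0.4)]
            )

    def test_adjacent_pair_rejected(self):
        with pytest.raises(syn.GeneratorError):
            syn.simulate_toy_trajectory(n_frames=1, planted_pairs=[(5, 6, 0.4)])

    def test_determinism(self):
        a = syn.simulate_toy_trajectory(n_frames=3, wobble_sd_nm=0.05, seed=4)
        b = syn.simulate_toy_trajectory(n_frames=3, wobble_sd_nm=0.05, seed=4)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestAffinityTable:
    def test_exact_class_composition_when_anchored(self, ac_model):
        from conftest import random_inserts

        seqs = random_inserts(72, seed=11)
        table = syn.simulate_affinity_table(ac_model, seqs, seed=1, n_high=20)
        high = table["censored"] | (table["tau_s"] >= 90.0)
        assert int(high.sum()) == 20

    def test_censoring_beyond_window(self, ac_model):
        from conftest import random_inserts

        seqs = random_inserts(40, seed=12)
        table = syn.simulate_affinity_table(
            ac_model, seqs, seed=2, n_high=10, censor_limit_s=600.0
        )
        assert table.loc[table["censored"], "tau_s"].isna().all()
        assert (table.loc[~table["censored"], "tau_s"] <= 600.0).all()


class TestMotifDataset:
    def test_balanced_and_order_dependent(self):
        seqs, labels = syn.generate_motif_dataset(200, seed=3)
        assert labels.sum() == 100
        motifs = ((4, "ACG"), (15, "TTC"), (24, "GCA"))
        for s, y in zip(seqs, labels):
            has = any(s[p : p + 3] == m for p, m in motifs)
            assert has == bool(y)
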