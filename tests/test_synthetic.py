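"""Generators: determinism, invariants, and agreement with analytic laws."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sposekit as sk
from sposekit.synthetic import odd_one_out_probabilities


class TestGroundTruthEmbedding:
    def test_zero_sparsity_has_no_exact_zeros(self):
        gt = sk.make_ground_truth_embedding(10, 3, sparsity=0.0, scale=1.0, seed=1)
        assert gt.weights.shape == (10, 3)
        assert np.all(gt.weights > 0)

    def test_same_seed_is_bit_identical(self):
        a = sk.make_ground_truth_embedding(30, 4, 0.5, 2.0, seed=7)
        b = sk.make_ground_truth_embedding(30, 4, 0.5, 2.0, seed=7)
        assert np.array_equal(a.weights, b.weights)

    def test_zero_fraction_concentrates_on_sparsity(self):
        gt = sk.make_ground_truth_embedding(2000, 10, sparsity=0.6, seed=3)
        assert np.mean(gt.weights == 0) == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_objects": 2, "n_dims": 3},
            {"n_objects": 10, "n_dims": 0},
            {"n_objects": 10, "n_dims": 3, "sparsity": 1.0},
            {"n_objects": 10, "n_dims": 3, "sparsity": -0.1},
            {"n_objects": 10, "n_dims": 3, "scale": 0.0},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            sk.make_ground_truth_embedding(**{"sparsity": 0.5, "scale": 1.0, **kwargs})


class TestTripletSampling:
    def test_three_objects_only_one_triple_exists(self):
        triples = sk.sample_triplet_tasks(3, 5, seed=0)
        for row in triples:
            assert sorted(row) == [0, 1, 2]

    def test_balanced_full_pass_covers_pairs_exactly(self):
        # 4 objects: C(4,3)=4 triples; one full pass touches each pair twice
        triples = sk.sample_triplet_tasks(4, 4, seed=1, balanced=True)
        stats = sk.pair_coverage_stats(triples, 4)
        assert stats.min == stats.max == 2

    @pytest.mark.parametrize("n_objects", [5, 6, 8])
    def test_balanced_multiple_of_all_triples_is_exactly_uniform(self, n_objects):
        n_all = sk.count_triplets(n_objects)
        n_trials = 2 * n_all
        triples = sk.sample_triplet_tasks(n_objects, n_trials, seed=2, balanced=True)
        stats = sk.pair_coverage_stats(triples, n_objects)
        expected = 3 * n_trials // sk.count_pairs(n_objects)
        assert stats.min == stats.max == expected

    @given(st.integers(3, 30), st.integers(1, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_members_always_distinct(self, n_objects, n_trials, seed):
        triples = sk.sample_triplet_tasks(n_objects, n_trials, seed=seed)
        assert triples.shape == (n_trials, 3)
        for row in triples:
            assert len(set(row)) == 3
            assert 0 <= min(row) and max(row) < n_objects

    def test_too_few_objects_raise(self):
        with pytest.raises(ValueError):
            sk.sample_triplet_tasks(2, 10, seed=0)


class TestSimulateChoices:
    def test_uniform_probabilities_for_zero_embedding(self):
        gt = sk.GroundTruthEmbedding(
            np.zeros((5, 2)), [f"o{i}" for i in range(5)], 0.0, 0
        )
        triples = sk.sample_triplet_tasks(5, 30_000, seed=1)
        data = sk.simulate_choices(gt, triples, seed=2)
        pos = np.argmax(data.triples == data.choices[:, None], axis=1)
        freq = np.bincount(pos, minlength=3) / len(data)
        assert np.allclose(freq, 1 / 3, atol=0.01)

    def test_deterministic_choice_picks_dominant_pair(self):
        # x_i = x_j = (10, 0) makes pair (i, j) overwhelmingly similar -> k odd
        w = np.array([[10.0, 0.0], [10.0, 0.0], [0.0, 0.0]])
        gt = sk.GroundTruthEmbedding(w, ["i", "j", "k"], 0.0, 0)
        data = sk.simulate_choices(gt, np.array([[0, 1, 2]]), deterministic=True)
        assert data.choices[0] == 2

    def test_same_seed_identical_choices(self):
        gt = sk.make_ground_truth_embedding(10, 3, 0.4, 1.0, seed=5)
        triples = sk.sample_triplet_tasks(10, 500, seed=6)
        a = sk.simulate_choices(gt, triples, seed=9)
        b = sk.simulate_choices(gt, triples, seed=9)
        assert np.array_equal(a.trials, b.trials)

    def test_empirical_frequencies_match_softmax_probabilities(self):
        # one fixed triple sampled 1e5 times: KS-style 3-standard-error check
        gt = sk.make_ground_truth_embedding(6, 3, 0.3, 1.5, seed=10)
        triples = np.tile([[0, 3, 5]], (100_000, 1))
        data = sk.simulate_choices(gt, triples, seed=11)
        p = odd_one_out_probabilities(gt.weights, triples[:1])[0]
        pos = np.argmax(data.triples == data.choices[:, None], axis=1)
        freq = np.bincount(pos, minlength=3) / len(data)
        se = np.sqrt(p * (1 - p) / len(data))
        assert np.all(np.abs(freq - p) <= 3 * se + 1e-12)

    def test_out_of_range_indices_raise(self, small_gt):
        with pytest.raises(ValueError):
            sk.simulate_choices(small_gt, np.array([[0, 1, 99]]))


class TestRepeatedMeasures:
    def test_zero_noise_repeats_identical(self):
        data = sk.simulate_repeated_measures(3, 10, 4, signal_sd=1.0, noise_sd=0.0, seed=0)
        assert np.allclose(data.responses.std(axis=2), 0.0)

    def test_variance_of_image_means_is_noise_over_repeats(self):
        data = sk.simulate_repeated_measures(
            1, 5000, 8, signal_sd=0.0, noise_sd=1.0, seed=1
        )
        var_means = data.responses.mean(axis=2).var(ddof=1)
        assert var_means == pytest.approx(1 / 8, rel=0.1)

    def test_deterministic_under_seed(self):
        a = sk.simulate_repeated_measures(2, 5, 3, seed=4)
        b = sk.simulate_repeated_measures(2, 5, 3, seed=4)
        assert np.array_equal(a.responses, b.responses)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            sk.simulate_repeated_measures(2, 5, 1, seed=0)
        with pytest.raises(ValueError):
            sk.simulate_repeated_measures(2, 5, 3, noise_sd=-1, seed=0)


class TestFusionSimulation:
    def test_pre_onset_sensors_are_pure_noise(self):
        time_axis = np.arange(-100.0, 301.0, 20.0)
        data = sk.simulate_fusion_data(
            400, 8, time_axis, 4, {"v": 100.0, "f": 200.0}, snr=2.0, seed=3
        )
        pre = time_axis < 100.0
        # single-correlation bound 3/sqrt(n); the max over all 80
        # sensor-timepoint pairs needs the wider multiple-comparison bound
        single_bound = 3 / np.sqrt(data.n_trials)
        max_bound = 4 / np.sqrt(data.n_trials)
        for roi in ("v", "f"):
            y = data.roi_responses[roi]
            rs = [
                np.corrcoef(data.sensor_data[:, :, t].T, y)[-1, :-1]
                for t in np.where(pre)[0]
            ]
            rs = np.abs(np.concatenate(rs))
            assert rs[0] < single_bound
            assert rs.max() < max_bound

    def test_noiseless_limit_feature_linearly_decodable(self):
        time_axis = np.arange(-100.0, 201.0, 50.0)
        data = sk.simulate_fusion_data(
            60, 5, time_axis, 3, {"v": 0.0}, snr=1e8, roi_noise_sd=0.0, seed=5
        )
        t = np.argmax(time_axis >= 0.0)
        X = data.sensor_data[:, :, t]
        y = data.roi_responses["v"]
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(60), X]), y, rcond=None)
        pred = np.column_stack([np.ones(60), X]) @ coef
        assert np.corrcoef(pred, y)[0, 1] > 1 - 1e-6

    def test_sessions_are_contiguous_blocks_with_min_size(self):
        data = sk.simulate_fusion_data(
            10, 2, np.arange(-100.0, 101.0, 50.0), 3, {"v": 0.0}, seed=6
        )
        assert np.all(np.diff(data.session_labels) >= 0)
        _, counts = np.unique(data.session_labels, return_counts=True)
        assert counts.min() >= 2

    def test_onset_outside_axis_raises(self):
        with pytest.raises(ValueError):
            sk.simulate_fusion_data(
                10, 2, np.arange(-100.0, 101.0, 50.0), 2, {"v": 999.0}, seed=0
            )


class TestCountingAndCoverage:
    def test_full_scale_design_counts(self):
        assert sk.count_triplets(1854) == 1_060_412_604
        assert sk.count_pairs(1854) == 1_717_731
        assert sk.count_triplets(3) == 1
        assert sk.count_pairs(2) == 1

    @given(st.integers(3, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_triple_pair_count_identity(self, n):
        assert sk.count_pairs(n) * (n - 2) == 3 * sk.count_triplets(n)

    def test_full_scale_mean_coverage(self):
        stats = sk.pair_coverage_stats(4_574_059, 1854)
        assert stats.mean == pytest.approx(7.99, abs=0.005)
        assert stats.min is None and stats.max is None

    def test_single_triple_coverage(self):
        stats = sk.pair_coverage_stats(np.array([[0, 1, 2]]), 3)
        assert stats.mean == stats.min == stats.max == 1

    def test_mean_matches_brute_force_tally(self):
        triples = sk.sample_triplet_tasks(20, 1000, seed=12)
        stats = sk.pair_coverage_stats(triples, 20)
        tally = {}
        for a, b, c in triples:
            for i, j in itertools.combinations(sorted((a, b, c)), 2):
                tally[(i, j)] = tally.get((i, j), 0) + 1
        assert stats.mean == pytest.approx(sum(tally.values()) / 190)
        assert stats.max == max(tally.values())

    def test_undersized_inputs_raise(self):
        with pytest.raises(ValueError):
            sk.count_triplets(2)
        with pytest.raises(ValueError):
            sk.count_pairs(1)
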