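"""Embedding model, loss, training invariants, and restart selection."""

import math
import warnings

import numpy as np
import pytest

import sposekit as sk
from sposekit.embedding import (
    _HAVE_NUMBA,
    _cross_entropy,
    prune_dimensions,
    sort_dimensions,
)
from sposekit.synthetic import TripletDataset


def _dataset(trials, n_objects):
    return TripletDataset(np.asarray(trials, dtype=np.int64), n_objects)


class TestTripletProbabilities:
    def test_equal_dot_products_give_uniform(self):
        w = np.ones((3, 2))
        p = sk.triplet_probabilities(w, (0, 1, 2))
        assert np.allclose(p, 1 / 3)

    def test_closed_form_softmax(self):
        # dot products (s_ij, s_ik, s_jk) = (1, 0, 0)
        w = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        p = sk.triplet_probabilities(w, (0, 1, 2))
        e = math.e
        assert p[0] == pytest.approx(e / (e + 2), rel=1e-12)
        assert p[1] == pytest.approx(1 / (e + 2), rel=1e-12)
        assert p[2] == pytest.approx(1 / (e + 2), rel=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        w = rng.random((8, 4))
        p = sk.triplet_probabilities(w, (1, 4, 6))
        assert sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_weights_raise(self):
        w = np.full((3, 2), np.inf)
        with pytest.raises(FloatingPointError):
            sk.triplet_probabilities(w, (0, 1, 2))


class TestSposeLoss:
    def test_zero_weights_give_log3_per_trial(self):
        batch = _dataset([[0, 1, 2, 0], [1, 2, 3, 3]], 4)
        loss = sk.spose_loss(np.zeros((4, 3)), batch, lam=0.0)
        assert loss == pytest.approx(math.log(3), rel=1e-12)

    def test_penalty_additivity(self):
        rng = np.random.default_rng(1)
        w = rng.random((5, 3))
        batch = _dataset([[0, 1, 2, 1], [2, 3, 4, 4]], 5)
        diff = sk.spose_loss(w, batch, 1.0) - sk.spose_loss(w, batch, 0.0)
        assert diff == pytest.approx(np.abs(w).sum() / 5, rel=1e-12)

    def test_perfect_prediction_limit(self):
        # pair (0,1) dominates -> choosing 2 is near-certain, loss near 0
        w = np.array([[30.0], [30.0], [0.0]]) ** 0.5
        batch = _dataset([[0, 1, 2, 2]], 3)
        assert sk.spose_loss(w, batch, 0.0) < 1e-10

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            sk.spose_loss(np.zeros((3, 1)), _dataset(np.empty((0, 4)), 3), 0.0)


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self):
        rng = np.random.default_rng(2)
        n_obj, d = 6, 4
        w = rng.random((n_obj, d)) + 0.05  # keep away from the hinge at 0
        triples = sk.sample_triplet_tasks(n_obj, 30, seed=3)
        gt = sk.GroundTruthEmbedding(w, [str(i) for i in range(n_obj)], 0, 0)
        batch = sk.simulate_choices(gt, triples, seed=4)
        lam = 0.01
        grad = sk.spose_loss_gradient(w, batch, lam)
        eps = 1e-6
        num = np.zeros_like(w)
        for i in range(n_obj):
            for j in range(d):
                wp, wm = w.copy(), w.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num[i, j] = (
                    sk.spose_loss(wp, batch, lam) - sk.spose_loss(wm, batch, lam)
                ) / (2 * eps)
        rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() < 1e-5


class TestTraining:
    def test_backends_agree(self, small_triplets):
        assert _HAVE_NUMBA
        cfg = sk.TrainingConfig(init_dims=6, lam=0.01, max_epochs=4, seed=5)
        a = sk.train_spose(small_triplets, cfg, backend="numba")
        b = sk.train_spose(small_triplets, cfg, backend="numpy")
        assert a.weights.shape == b.weights.shape
        assert np.abs(a.weights - b.weights).max() < 1e-12

    def test_seeded_determinism(self, small_triplets):
        cfg = sk.TrainingConfig(init_dims=6, lam=0.01, max_epochs=5, seed=6)
        a = sk.train_spose(small_triplets, cfg)
        b = sk.train_spose(small_triplets, cfg)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.train_loss_history, b.train_loss_history)

    def test_nonnegative_and_sorted(self, tiny_fit):
        assert np.all(tiny_fit.weights >= 0)
        sums = tiny_fit.weights.sum(axis=0)
        assert np.all(np.diff(sums) <= 1e-12)
        # every retained dimension clears the pruning threshold somewhere
        assert np.all(tiny_fit.weights.max(axis=0) >= tiny_fit.config.prune_threshold)

    def test_huge_penalty_prunes_everything(self, small_triplets):
        # Adam steps are capped near the learning rate, so driving every
        # weight from its [0,1) init to 0 needs > 1/lr steps in total
        cfg = sk.TrainingConfig(init_dims=5, lam=1000.0, max_epochs=100, seed=0)
        with pytest.warns(UserWarning, match="pruned"):
            emb = sk.train_spose(small_triplets, cfg)
        assert emb.n_dims == 0

    def test_pruning_idempotent_and_sorting(self):
        rng = np.random.default_rng(7)
        w = rng.random((6, 5))
        w[:, 2] *= 0.01  # exclusively below threshold
        once = prune_dimensions(w, 0.1)
        assert np.array_equal(once, prune_dimensions(once, 0.1))
        assert once.shape[1] == 4
        s, order = sort_dimensions(once)
        assert np.all(np.diff(s.sum(axis=0)) <= 0)

    def test_unknown_backend_raises(self, small_triplets):
        with pytest.raises(ValueError):
            sk.train_spose(small_triplets, sk.TrainingConfig(), backend="gpu")

    def test_missing_object_warns(self):
        data = _dataset([[0, 1, 2, 0]] * 10, 4)  # object 3 never appears
        cfg = sk.TrainingConfig(init_dims=3, max_epochs=2, seed=0, val_fraction=0.0)
        with pytest.warns(UserWarning, match="never occur"):
            sk.train_spose(data, cfg)


class TestSelectLambda:
    def test_selection_returns_grid_element(self, small_triplets):
        cfg = sk.TrainingConfig(init_dims=5, max_epochs=10, seed=1)
        lam, losses = sk.select_lambda(small_triplets, [0.0, 0.01], 2, cfg)
        assert lam in (0.0, 0.01)
        assert losses.shape == (2, 2)

    def test_negative_grid_raises(self, small_triplets):
        with pytest.raises(ValueError):
            sk.select_lambda(small_triplets, [-0.1, 0.0], 2)

    def test_selected_lambda_not_worse_than_zero(self, small_gt, small_triplets):
        # on data from a sparse generator, held-out CE at the selected lam
        # must not exceed held-out CE at lam=0 by more than 1 SE
        cfg = sk.TrainingConfig(init_dims=8, max_epochs=40, seed=2)
        lam, losses = sk.select_lambda(small_triplets, [0.0, 0.01, 0.04], 2, cfg)
        mean = losses.mean(axis=1)
        se = losses.std(axis=1, ddof=1) / np.sqrt(losses.shape[1])
        sel = [0.0, 0.01, 0.04].index(lam)
        assert mean[sel] <= mean[0] + se[0] + 1e-12


class TestReproducibility:
    def test_exact_copy_scores_one(self, tiny_fit):
        scores = sk.dimension_reproducibility(tiny_fit, [tiny_fit])
        assert np.all(scores > 1 - 1e-5)

    def test_column_permutation_invariance(self, tiny_fit):
        permuted = tiny_fit.weights[:, ::-1].copy()
        scores = sk.dimension_reproducibility(tiny_fit, [permuted])
        assert np.all(scores > 1 - 1e-5)

    def test_shared_dimension_beats_noise(self):
        rng = np.random.default_rng(8)
        shared = rng.random(40)
        embs = []
        for _ in range(3):
            noise = rng.random((40, 2))
            embs.append(np.column_stack([shared + 0.01 * rng.random(40), noise]))
        scores = sk.dimension_reproducibility(embs[0], embs[1:])
        assert scores[0] > scores[1] and scores[0] > scores[2]

    def test_select_identical_embeddings_tie_lowest(self, tiny_fit):
        idx, best, report = sk.select_most_reproducible([tiny_fit, tiny_fit, tiny_fit])
        assert idx == 0 and best is tiny_fit
        assert report.selected_index == 0

    def test_consensus_beats_noise_embedding(self):
        rng = np.random.default_rng(9)
        consensus = rng.random((30, 3))
        jittered = [consensus + 0.01 * rng.random((30, 3)) for _ in range(3)]
        noise = rng.random((30, 3))
        embs = jittered + [noise]
        idx, _, report = sk.select_most_reproducible(embs)
        assert idx != 3
        assert report.per_embedding_mean[3] < report.per_embedding_mean[idx]

    def test_single_embedding_raises(self, tiny_fit):
        with pytest.raises(ValueError):
            sk.select_most_reproducible([tiny_fit])

    def test_zero_variance_dimension_warns(self):
        target = np.column_stack([np.zeros(10), np.arange(10.0)])
        other = np.random.default_rng(0).random((10, 2))
        with pytest.warns(UserWarning, match="zero variance"):
            scores = sk.dimension_reproducibility(target, [other])
        assert scores[0] == 0.0


class TestEvaluateAccuracy:
    def test_self_consistency_on_deterministic_choices(self, small_gt):
        triples = sk.sample_triplet_tasks(small_gt.n_objects, 500, seed=10)
        data = sk.simulate_choices(small_gt, triples, deterministic=True)
        assert sk.evaluate_accuracy(small_gt.weights, data) == 100.0

    def test_chance_level_for_uninformative_embedding(self):
        gt = sk.GroundTruthEmbedding(np.zeros((20, 2)), [str(i) for i in range(20)], 0, 0)
        triples = sk.sample_triplet_tasks(20, 20_000, seed=11)
        data = sk.simulate_choices(gt, triples, seed=12)
        rng = np.random.default_rng(13)
        w = rng.random((20, 3))  # arbitrary embedding vs purely random choices
        acc = sk.evaluate_accuracy(w, data)
        assert acc == pytest.approx(100 / 3, abs=1.0)

    def test_fitted_accuracy_below_bayes(self, small_gt, small_triplets, tiny_fit):
        acc = sk.evaluate_accuracy(tiny_fit, small_triplets)
        bayes = sk.bayes_accuracy(small_gt.weights, small_triplets.triples)
        se = 100 / np.sqrt(len(small_triplets))
        assert acc <= bayes + 2 * se

    def test_empty_test_set_raises(self, tiny_fit):
        with pytest.raises(ValueError):
            sk.evaluate_accuracy(tiny_fit, _dataset(np.empty((0, 4)), 3))
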