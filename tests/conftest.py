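import numpy as np
import pytest

import sposekit as sk


@pytest.fixture(scope="session")
def small_gt():
    """A 12-object, 3-dimensional sparse ground-truth embedding."""
    return sk.make_ground_truth_embedding(12, 3, sparsity=0.5, scale=1.5, seed=42)


@pytest.fixture(scope="session")
def small_triplets(small_gt):
    """2,000 sampled softmax choices over the small ground truth."""
    triples = sk.sample_triplet_tasks(small_gt.n_objects, 2000, seed=7)
    return sk.simulate_choices(small_gt, triples, seed=8)


@pytest.fixture(scope="session")
def tiny_fit(small_triplets):
    """A quick low-dimensional fit used by tests that need any valid embedding."""
    cfg = sk.TrainingConfig(init_dims=8, lam=0.01, max_epochs=60, seed=0)
    return sk.train_spose(small_triplets, cfg)
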