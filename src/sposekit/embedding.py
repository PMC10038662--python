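"""Sparse positive similarity embedding (SPoSE) from triplet choices.

The model represents every object as a non-negative vector. For a triplet
(a, b, c) the dot products of the three pairs are passed through a softmax
(no temperature), and the probability that an object is picked as the
odd-one-out equals the softmax weight of the *remaining* pair. Training
minimizes the cross-entropy of the observed choices plus an L1 penalty that
induces sparsity, using Adam with the weights projected to be non-negative
after every update. After training, dimensions whose weights are all below
a threshold are pruned, and the survivors are sorted by descending column
sum.

Because the optimization is stochastic, the standard protocol fits many
random restarts and keeps the one whose dimensions are most reproducible
across the rest (average Fisher-z-transformed best-match Pearson
correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import TripletDataset, odd_one_out_probabilities, _pair_scores


@dataclass
class TrainingConfig:
    """Hyperparameters of the embedding fit.

    ``lam`` is the L1 trade-off λ; the penalty is λ·Σ|w| / n_objects so that
    λ keeps a comparable meaning across object-set sizes. ``init_dims``
    dimensions are initialized uniformly on [0, 1). Dimensions whose weights
    all end below ``prune_threshold`` are removed after training.

    By default training runs for ``max_epochs`` full passes: the L1-driven
    shrinkage of redundant dimensions continues long after the validation
    cross-entropy has flattened, so stopping on validation loss alone leaves
    the embedding under-sparsified. Setting ``early_stop_patience`` enables
    an optional validation-loss stop (no improvement beyond
    ``early_stop_tol`` for that many epochs) for quick exploratory fits.
    """

    init_dims: int = 90
    lam: float = 0.00385
    batch_size: int = 100
    learning_rate: float = 0.001
    max_epochs: int = 500
    prune_threshold: float = 0.1
    seed: int = 0
    val_fraction: float = 0.1
    early_stop_patience: int | None = None
    early_stop_tol: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.prune_threshold <= 0:
            raise ValueError("prune_threshold must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.init_dims < 1:
            raise ValueError("init_dims must be >= 1")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class TrainedEmbedding:
    """A fitted, pruned, column-sorted non-negative embedding."""

    weights: np.ndarray
    dim_order: np.ndarray
    config: TrainingConfig
    train_loss_history: np.ndarray
    val_loss_history: np.ndarray | None = None
    dim_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        sums = self.weights.sum(axis=0)
        if sums.size > 1 and np.any(np.diff(sums) > 1e-9):
            raise ValueError("columns must be sorted by non-increasing sum")

    @property
    def n_objects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_dims(self) -> int:
        return self.weights.shape[1]


@dataclass
class ReproducibilityReport:
    """Reproducibility of each restart's dimensions across the other restarts."""

    per_dim_scores: list[np.ndarray]
    per_embedding_mean: np.ndarray
    selected_index: int


# ---------------------------------------------------------------------------
# Model: probabilities and loss
# ---------------------------------------------------------------------------

def triplet_probabilities(weights: np.ndarray, triple) -> tuple[float, float, float]:
    """Softmax pair probabilities for one triple (i, j, k).

    Returns ``(p_pair_ij, p_pair_ik, p_pair_jk)``: the softmax of the three
    pairwise dot products, i.e. the probability that each pair is judged
    most similar — equivalently that the excluded third object is the
    odd-one-out. The three values sum to 1.
    """
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise FloatingPointError("embedding weights must be finite")
    i, j, k = triple
    if len({i, j, k}) != 3:
        raise ValueError("triple members must be distinct")
    # probability that k is odd-one-out = softmax weight of pair (i, j)
    p = odd_one_out_probabilities(weights, np.array([[i, j, k]]))[0]
    return float(p[2]), float(p[1]), float(p[0])


def _choice_position(trials: np.ndarray) -> np.ndarray:
    """Column (0, 1 or 2) of the chosen odd-one-out within each trial row."""
    return np.argmax(trials[:, :3] == trials[:, 3][:, None], axis=1)


def _cross_entropy(weights: np.ndarray, trials: np.ndarray) -> float:
    probs = odd_one_out_probabilities(weights, trials[:, :3])
    pos = _choice_position(trials)
    p_obs = probs[np.arange(trials.shape[0]), pos]
    return float(-np.mean(np.log(np.maximum(p_obs, 1e-300))))


def spose_loss(weights: np.ndarray, batch: TripletDataset, lam: float) -> float:
    """Mean cross-entropy of observed choices plus λ·Σ|w| / n_objects."""
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    weights = np.asarray(weights, dtype=float)
    ce = _cross_entropy(weights, batch.trials)
    penalty = lam * np.abs(weights).sum() / weights.shape[0]
    return ce + penalty


def spose_loss_gradient(
    weights: np.ndarray, batch: TripletDataset, lam: float
) -> np.ndarray:
    """Analytic gradient of :func:`spose_loss` with respect to the weights.

    Uses the softmax identity dL/ds_pair = p_pair − 1[pair observed], then
    chains through the dot products. The L1 term contributes λ/n_objects for
    positive weights (the training loop keeps weights ≥ 0, so the
    subgradient sign is fixed).
    """
    weights = np.asarray(weights, dtype=float)
    trials = batch.trials
    triples = trials[:, :3]
    probs = odd_one_out_probabilities(weights, triples)
    pos = _choice_position(trials)
    # residual on the odd-one-out probabilities == residual on pair scores:
    # column m of probs is the softmax of the pair excluding member m.
    resid = probs.copy()
    resid[np.arange(trials.shape[0]), pos] -= 1.0
    xa = weights[triples[:, 0]]
    xb = weights[triples[:, 1]]
    xc = weights[triples[:, 2]]
    # score columns: 0 -> s_bc, 1 -> s_ac, 2 -> s_ab
    g_bc = resid[:, 0:1]
    g_ac = resid[:, 1:2]
    g_ab = resid[:, 2:3]
    grad = np.zeros_like(weights)
    np.add.at(grad, triples[:, 0], g_ab * xb + g_ac * xc)
    np.add.at(grad, triples[:, 1], g_ab * xa + g_bc * xc)
    np.add.at(grad, triples[:, 2], g_ac * xa + g_bc * xb)
    grad /= trials.shape[0]
    grad += lam / weights.shape[0] * np.where(weights > 0, 1.0, 0.0)
    return grad


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

try:  # optional JIT of the minibatch loop; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _run_epoch_jit(w, m, v, t, tri, pos, order, batch_size,
                   lr, b1, b2, eps, lam_per_obj):  # pragma: no cover - JIT
    """One epoch of projected Adam over shuffled minibatches (in place).

    Must stay numerically equivalent to one pass of Adam steps on
    :func:`spose_loss_gradient`; the agreement is asserted in the tests.
    Returns (new t, summed cross-entropy over trials).
    """
    n_train = tri.shape[0]
    n_obj, d = w.shape
    total_ce = 0.0
    grad = np.zeros((n_obj, d))
    for start in range(0, n_train, batch_size):
        end = min(start + batch_size, n_train)
        bs = end - start
        grad[:, :] = 0.0
        for ii in range(start, end):
            r = order[ii]
            a, b, c = tri[r, 0], tri[r, 1], tri[r, 2]
            s_ab = 0.0
            s_ac = 0.0
            s_bc = 0.0
            for j in range(d):
                s_ab += w[a, j] * w[b, j]
                s_ac += w[a, j] * w[c, j]
                s_bc += w[b, j] * w[c, j]
            mx = max(s_ab, max(s_ac, s_bc))
            e_bc = np.exp(s_bc - mx)
            e_ac = np.exp(s_ac - mx)
            e_ab = np.exp(s_ab - mx)
            z = e_bc + e_ac + e_ab
            p0 = e_bc / z  # member a odd
            p1 = e_ac / z  # member b odd
            p2 = e_ab / z  # member c odd
            pk = pos[r]
            p_obs = p0 if pk == 0 else (p1 if pk == 1 else p2)
            total_ce += -np.log(max(p_obs, 1e-300))
            g0 = p0 - (1.0 if pk == 0 else 0.0)
            g1 = p1 - (1.0 if pk == 1 else 0.0)
            g2 = p2 - (1.0 if pk == 2 else 0.0)
            for j in range(d):
                grad[a, j] += g2 * w[b, j] + g1 * w[c, j]
                grad[b, j] += g2 * w[a, j] + g0 * w[c, j]
                grad[c, j] += g1 * w[a, j] + g0 * w[b, j]
        t += 1
        bc1 = 1.0 - b1**t
        bc2 = 1.0 - b2**t
        inv = 1.0 / bs
        for i in range(n_obj):
            for j in range(d):
                g = grad[i, j] * inv
                if w[i, j] > 0:
                    g += lam_per_obj
                m[i, j] = b1 * m[i, j] + (1.0 - b1) * g
                v[i, j] = b2 * v[i, j] + (1.0 - b2) * g * g
                # flush decayed moments to zero before they go subnormal
                # (subnormal arithmetic is orders of magnitude slower)
                if -1e-30 < m[i, j] < 1e-30:
                    m[i, j] = 0.0
                if v[i, j] < 1e-30:
                    v[i, j] = 0.0
                w[i, j] -= lr * (m[i, j] / bc1) / (np.sqrt(v[i, j] / bc2) + eps)
                if w[i, j] < 0:
                    w[i, j] = 0.0
    return t, total_ce


def _run_epoch_numpy(w, m, v, t, tri, pos, order, batch_size,
                     lr, b1, b2, eps, lam_per_obj):
    """Reference numpy implementation of :func:`_run_epoch_jit`."""
    n_train = tri.shape[0]
    total_ce = 0.0
    for start in range(0, n_train, batch_size):
        rows = order[start:start + batch_size]
        bt = tri[rows]
        bp = pos[rows]
        probs = odd_one_out_probabilities(w, bt)
        p_obs = probs[np.arange(bt.shape[0]), bp]
        total_ce += float(-np.log(np.maximum(p_obs, 1e-300)).sum())
        resid = probs.copy()
        resid[np.arange(bt.shape[0]), bp] -= 1.0
        xa, xb, xc = w[bt[:, 0]], w[bt[:, 1]], w[bt[:, 2]]
        g_bc, g_ac, g_ab = resid[:, 0:1], resid[:, 1:2], resid[:, 2:3]
        grad = np.zeros_like(w)
        np.add.at(grad, bt[:, 0], g_ab * xb + g_ac * xc)
        np.add.at(grad, bt[:, 1], g_ab * xa + g_bc * xc)
        np.add.at(grad, bt[:, 2], g_ac * xa + g_bc * xb)
        grad /= bt.shape[0]
        grad += lam_per_obj * (w > 0)
        t += 1
        m *= b1
        m += (1 - b1) * grad
        v *= b2
        v += (1 - b2) * grad * grad
        # flush decayed moments before they go subnormal (keeps parity with
        # the JIT backend and avoids the subnormal-arithmetic slowdown)
        m[np.abs(m) < 1e-30] = 0.0
        v[v < 1e-30] = 0.0
        w -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        np.maximum(w, 0.0, out=w)
    return t, total_ce


def prune_dimensions(weights: np.ndarray, threshold: float) -> np.ndarray:
    """Drop dimensions whose weights are exclusively below ``threshold``."""
    keep = (weights >= threshold).any(axis=0)
    return weights[:, keep]


def sort_dimensions(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order dimensions by descending column sum; stable for ties."""
    order = np.argsort(-weights.sum(axis=0), kind="stable")
    return weights[:, order], order


def train_spose(
    data: TripletDataset,
    config: TrainingConfig,
    backend: str = "auto",
) -> TrainedEmbedding:
    """Fit the embedding by projected Adam on minibatches of triplets.

    Trials are shuffled each epoch; weights are clipped at zero after every
    update, so the embedding stays non-negative throughout. A
    ``val_fraction`` split of the trials is held out to monitor
    cross-entropy (and to stop early when ``early_stop_patience`` is set).
    ``backend`` selects the inner-loop implementation: "numba" (JIT,
    default when available), "numpy" (reference), or "auto".
    """
    if data.n_objects < 3:
        raise ValueError("need at least 3 objects")
    if backend not in ("auto", "numba", "numpy"):
        raise ValueError("backend must be 'auto', 'numba' or 'numpy'")
    run_epoch = _run_epoch_numpy
    if backend == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is not installed")
    if _HAVE_NUMBA and backend in ("auto", "numba"):
        run_epoch = _run_epoch_jit
    present = np.bincount(data.triples.ravel(), minlength=data.n_objects)
    if np.any(present == 0):
        warnings.warn(
            f"{int((present == 0).sum())} object(s) never occur in the triplets; "
            "their rows are unconstrained",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    n = len(data)
    order = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_trials = data.trials[order[:n_val]]
    train_trials = data.trials[order[n_val:]]
    if train_trials.shape[0] == 0:
        raise ValueError("no training trials left after validation split")

    w = rng.random((data.n_objects, config.init_dims))
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    t = 0
    lam = config.lam
    n_train = train_trials.shape[0]
    tri = np.ascontiguousarray(train_trials[:, :3])
    pos = _choice_position(train_trials)

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    stale = 0
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n_train)
        t, epoch_ce = run_epoch(
            w, m, v, t, tri, pos, perm, config.batch_size,
            config.learning_rate, config.adam_beta1, config.adam_beta2,
            config.adam_eps, lam / data.n_objects,
        )
        epoch_loss = epoch_ce / n_train + lam * np.abs(w).sum() / w.shape[0]
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        train_hist.append(epoch_loss)
        if n_val:
            val_ce = _cross_entropy(w, val_trials)
            val_hist.append(val_ce)
            if val_ce < best_val - config.early_stop_tol:
                best_val = val_ce
                stale = 0
            elif config.early_stop_patience is not None:
                stale += 1
                if stale >= config.early_stop_patience:
                    break

    pruned = prune_dimensions(w, config.prune_threshold)
    if pruned.shape[1] == 0:
        warnings.warn("all dimensions pruned; returning a 0-dimensional embedding",
                      stacklevel=2)
    sorted_w, order = sort_dimensions(pruned)
    return TrainedEmbedding(
        weights=sorted_w,
        dim_order=order,
        config=config,
        train_loss_history=np.asarray(train_hist),
        val_loss_history=np.asarray(val_hist) if n_val else None,
    )


def select_lambda(
    data: TripletDataset,
    grid,
    n_folds: int = 5,
    config: TrainingConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Pick λ by k-fold cross-validation on held-out cross-entropy.

    Returns the grid element with the lowest mean held-out cross-entropy
    (ties broken toward the smaller λ) together with the per-(λ, fold) loss
    table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(g < 0 for g in grid):
        raise ValueError("grid entries must be non-negative")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if config is None:
        config = TrainingConfig()
    rng = np.random.default_rng(config.seed)
    n = len(data)
    fold_of = rng.permutation(n) % n_folds
    losses = np.empty((len(grid), n_folds))
    for gi, lam in enumerate(grid):
        for fold in range(n_folds):
            train = data.subset(fold_of != fold)
            test = data.subset(fold_of == fold)
            fitted = train_spose(train, replace(config, lam=lam))
            if fitted.n_dims == 0:
                losses[gi, fold] = np.log(3.0)  # uniform-guess cross-entropy
            else:
                losses[gi, fold] = _cross_entropy(fitted.weights, test.trials)
    mean_loss = losses.mean(axis=1)
    order = np.argsort(grid, kind="stable")
    best = min(order, key=lambda i: (mean_loss[i], grid[i]))
    return float(grid[int(best)]), losses


# ---------------------------------------------------------------------------
# Reproducibility-based model selection
# ---------------------------------------------------------------------------

_CLIP = 1.0 - 1e-7


def _best_match_r(dim: np.ndarray, other: np.ndarray) -> float:
    """Max Pearson r of one dimension against all columns of another embedding."""
    sd = dim.std()
    if sd == 0 or other.shape[1] == 0:
        return 0.0
    d = (dim - dim.mean()) / sd
    o = other - other.mean(axis=0)
    o_sd = other.std(axis=0)
    valid = o_sd > 0
    if not valid.any():
        return 0.0
    r = (o[:, valid] * d[:, None]).mean(axis=0) / o_sd[valid]
    return float(r.max())


def dimension_reproducibility(
    target: TrainedEmbedding | np.ndarray,
    others,
) -> np.ndarray:
    """Reproducibility index of each target dimension across other restarts.

    For each dimension of ``target``, find the most similar dimension
    (maximal Pearson r, matching with replacement) in every other
    embedding, Fisher-z transform the correlations (clipped to
    ±(1 − 1e-7)), average the z's, and back-transform to r.
    """
    others = list(others)
    if not others:
        raise ValueError("need at least one other embedding")
    tw = target.weights if isinstance(target, TrainedEmbedding) else np.asarray(target)
    ows = [o.weights if isinstance(o, TrainedEmbedding) else np.asarray(o) for o in others]
    for ow in ows:
        if ow.shape[0] != tw.shape[0]:
            raise ValueError("all embeddings must share the same objects")
    scores = np.empty(tw.shape[1])
    for d in range(tw.shape[1]):
        col = tw[:, d]
        if col.std() == 0:
            warnings.warn(f"dimension {d} has zero variance; scored as r=0",
                          stacklevel=2)
        rs = np.array([_best_match_r(col, ow) for ow in ows])
        z = np.arctanh(np.clip(rs, -_CLIP, _CLIP))
        scores[d] = np.tanh(z.mean())
    return scores


def select_most_reproducible(
    embeddings,
) -> tuple[int, TrainedEmbedding, ReproducibilityReport]:
    """Pick the restart whose dimensions best replicate across the others.

    Each embedding's score is the mean of its per-dimension reproducibility
    indices against all remaining embeddings; the argmax wins (ties toward
    the lowest index). Zero-dimensional restarts score −inf.
    """
    embeddings = list(embeddings)
    if len(embeddings) < 2:
        raise ValueError("need at least 2 embeddings to compare")
    per_dim: list[np.ndarray] = []
    means = np.empty(len(embeddings))
    for i, emb in enumerate(embeddings):
        others = embeddings[:i] + embeddings[i + 1:]
        w = emb.weights if isinstance(emb, TrainedEmbedding) else np.asarray(emb)
        if w.shape[1] == 0:
            per_dim.append(np.empty(0))
            means[i] = -np.inf
            continue
        scores = dimension_reproducibility(emb, others)
        per_dim.append(scores)
        means[i] = scores.mean()
    selected = int(np.argmax(means))
    report = ReproducibilityReport(per_dim, means, selected)
    return selected, embeddings[selected], report


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict_choices(weights: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Most probable odd-one-out per triple; ties -> lowest object index."""
    from .synthetic import _argmax_lowest_object

    triples = np.asarray(triples, dtype=np.int64)
    probs = odd_one_out_probabilities(weights, triples)
    positions = _argmax_lowest_object(probs, triples)
    return triples[np.arange(triples.shape[0]), positions]


def evaluate_accuracy(
    embedding: TrainedEmbedding | np.ndarray, test: TripletDataset
) -> float:
    """Percent of held-out triplets whose odd-one-out is predicted correctly."""
    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    w = embedding.weights if isinstance(embedding, TrainedEmbedding) else np.asarray(embedding)
    predicted = predict_choices(w, test.triples)
    return 100.0 * float(np.mean(predicted == test.choices))


def bayes_accuracy(weights: np.ndarray, triples: np.ndarray) -> float:
    """Best achievable percent accuracy on softmax-sampled choices.

    For choices sampled from the generative softmax model, the optimal
    predictor picks the most probable outcome, so the expected accuracy is
    the mean of the per-triple maximum probability.
    """
    probs = odd_one_out_probabilities(weights, np.asarray(triples, dtype=np.int64))
    return 100.0 * float(probs.max(axis=1).mean())


def train_test_split(
    data: TripletDataset, test_fraction: float = 0.1, seed: int = 0
) -> tuple[TripletDataset, TripletDataset]:
    """Uniform random trial split (default 90-10)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_test = int(round(test_fraction * len(data)))
    return data.subset(order[n_test:]), data.subset(order[:n_test])
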