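"""Choice-probability similarity matrices and representational similarity.

Under the softmax triplet model, the similarity of objects i and j can be
defined behaviorally: the probability that a third object k would be picked
as the odd-one-out of the triplet {i, j, k}, averaged over all possible k in
a context set. Restricting the context (e.g. to one superordinate category)
yields context-constrained similarities that differ from sub-setting the
full-context matrix — the model's similarities are context dependent.

The similarity matrix converts to a representational dissimilarity matrix
(RDM) as 1 − similarity; two RDMs are compared by Pearson correlation of
their strictly-lower-triangular parts, with object-level bootstrap
resampling for confidence intervals and a majority-vote improvement test
across multiple datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import TrainedEmbedding


@dataclass
class SimilarityMatrix:
    """Symmetric choice-probability similarity in [0, 1].

    The diagonal is undefined (an object has no odd-one-out probability
    against itself); it is stored as 1 by convention and excluded from all
    statistics.
    """

    values: np.ndarray
    object_ids: list[str]
    context_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(self.values)
        off = ~np.eye(self.values.shape[0], dtype=bool)
        if np.any((self.values[off] < 0) | (self.values[off] > 1)):
            raise ValueError("similarities must lie in [0, 1]")


@dataclass
class RDM:
    """Symmetric representational dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    object_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(self.values)
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("RDM diagonal must be zero")


def _check_square_symmetric(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")


def n_pairs(n: int) -> int:
    """Number of strictly-lower-triangular entries, C(n, 2)."""
    if n < 2:
        raise ValueError("need at least 2 objects")
    return math.comb(n, 2)


def lower_tri(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangular entries in row-major order, length C(n, 2)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return m[np.tril_indices(m.shape[0], k=-1)]


def choice_prob_similarity(
    weights: np.ndarray | TrainedEmbedding,
    context: np.ndarray | None = None,
    object_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Similarity of each object pair as the mean odd-one-out probability.

    ``sim(i, j)`` is the probability that a third object k is judged the
    odd-one-out of {i, j, k} under the softmax of pairwise dot products,
    averaged over all k in the context except i and j. ``context`` (object
    indices into ``weights``) defaults to all objects; smaller contexts give
    category-constrained similarities.
    """
    w = weights.weights if isinstance(weights, TrainedEmbedding) else np.asarray(weights, dtype=float)
    n_total = w.shape[0]
    if context is None:
        context = np.arange(n_total)
    context = np.asarray(context, dtype=np.int64)
    if context.size < 3:
        raise ValueError("context must contain at least 3 objects")
    if context.min() < 0 or context.max() >= n_total:
        raise ValueError("context indices out of range")
    if np.unique(context).size != context.size:
        raise ValueError("context indices must be distinct")
    M = w[context]
    m = context.size
    S = M @ M.T
    total = np.zeros((m, m))
    for k in range(m):
        s_ik = S[:, k]
        mx = np.maximum(S, np.maximum(s_ik[:, None], s_ik[None, :]))
        num = np.exp(S - mx)
        denom = num + np.exp(s_ik[:, None] - mx) + np.exp(s_ik[None, :] - mx)
        p_k = num / denom
        p_k[k, :] = 0.0  # triples must have three distinct members
        p_k[:, k] = 0.0
        total += p_k
    sim = total / (m - 2)
    np.fill_diagonal(sim, 1.0)
    sim = 0.5 * (sim + sim.T)  # exact symmetry despite float round-off
    if object_ids is None:
        object_ids = [f"object_{i:04d}" for i in context]
    return SimilarityMatrix(sim, object_ids, context_ids=[str(i) for i in context])


def similarity_to_rdm(S: SimilarityMatrix) -> RDM:
    """Dissimilarity = 1 − similarity off-diagonal; zero diagonal."""
    d = 1.0 - S.values
    np.fill_diagonal(d, 0.0)
    return RDM(d, list(S.object_ids))


def rsa_pearson(rdm_a: RDM | np.ndarray, rdm_b: RDM | np.ndarray) -> float:
    """Pearson correlation of the lower-triangular parts of two RDMs."""
    a = rdm_a.values if isinstance(rdm_a, RDM) else np.asarray(rdm_a, dtype=float)
    b = rdm_b.values if isinstance(rdm_b, RDM) else np.asarray(rdm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RDMs must have matching shapes")
    va, vb = lower_tri(a), lower_tri(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined: zero variance in an RDM")
    return float(np.corrcoef(va, vb)[0, 1])


def bootstrap_object_rsa(
    rdm_a: RDM | np.ndarray,
    rdm_b: RDM | np.ndarray,
    unique_object_ids,
    n_boot: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Object-level bootstrap of the RSA correlation.

    Rows sharing an entry of ``unique_object_ids`` refer to the same
    underlying object (e.g. multiple images of one concept) and are
    resampled as a unit: each draw samples the distinct objects with
    replacement, takes all their rows, and recomputes the lower-triangular
    Pearson correlation on the induced sub-matrices. Pairs between
    duplicated copies of the same drawn row (exact self-pairs) are excluded;
    draws with fewer than 3 distinct objects are redrawn.

    Returns the bootstrap correlation samples and their (2.5, 97.5)
    percentile interval.
    """
    a = rdm_a.values if isinstance(rdm_a, RDM) else np.asarray(rdm_a, dtype=float)
    b = rdm_b.values if isinstance(rdm_b, RDM) else np.asarray(rdm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RDMs must have matching shapes")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ids = list(unique_object_ids)
    if len(ids) != a.shape[0]:
        raise ValueError("unique_object_ids must map every matrix row")
    labels = {}
    for row, obj in enumerate(ids):
        labels.setdefault(obj, []).append(row)
    objects = list(labels)
    if len(objects) < 3:
        raise ValueError("need at least 3 distinct objects")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    for d in range(n_boot):
        while True:
            drawn = rng.integers(0, len(objects), size=len(objects))
            if np.unique(drawn).size >= 3:
                break
        rows = np.concatenate([labels[objects[o]] for o in drawn]).astype(np.int64)
        sub_a = a[np.ix_(rows, rows)]
        sub_b = b[np.ix_(rows, rows)]
        p, q = np.tril_indices(rows.size, k=-1)
        keep = rows[p] != rows[q]  # drop exact self-pairs from duplication
        va, vb = sub_a[p[keep], q[keep]], sub_b[p[keep], q[keep]]
        if va.std() == 0 or vb.std() == 0:
            samples[d] = np.nan
        else:
            samples[d] = np.corrcoef(va, vb)[0, 1]
    valid = samples[~np.isnan(samples)]
    ci = tuple(np.percentile(valid, [2.5, 97.5]))
    return samples, (float(ci[0]), float(ci[1]))


def improvement_test(boot_new, boot_old) -> tuple[float, float]:
    """Majority-vote test that a new model improves RSA across datasets.

    ``boot_new`` and ``boot_old`` are aligned (n_datasets, n_draws) arrays
    of bootstrap correlations. A draw counts as an improvement when more
    than half the datasets show ``r_new > r_old`` (ties are
    non-improvements); the p-value is the fraction of non-improvement
    draws. Also returns the mean paired improvement over datasets and
    draws.
    """
    new = np.asarray(boot_new, dtype=float)
    old = np.asarray(boot_old, dtype=float)
    if new.shape != old.shape:
        raise ValueError("bootstrap arrays must be aligned (same shape)")
    if new.ndim != 2 or new.shape[0] < 2:
        raise ValueError("need >= 2 datasets with aligned bootstrap draws")
    d = new.shape[0]
    improved = (new > old).sum(axis=0) > d / 2
    p_value = float(np.mean(~improved))
    mean_improvement = float(np.mean(new - old))
    return p_value, mean_improvement
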