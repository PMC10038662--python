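"""Synthetic inputs with known ground truth for the triplet-embedding pipeline.

Every generator here produces one of the pipeline's input objects from a known
generative model, so that downstream estimators (embedding training, noise
ceilings, extrapolation, fusion) can be validated against ground truth:

* a sparse non-negative object embedding (the ground truth an embedding
  fit should recover),
* triplet odd-one-out tasks with roughly uniform pair coverage, and choices
  sampled from the softmax-of-dot-products model run forward,
* repeated channel x image responses under a Gaussian signal-plus-noise model
  (fixture for noise-ceiling estimation),
* sensor time series in which stimulus information about a brain region
  becomes available only after a region-specific latency (fixture for
  time-resolved sensor-to-region regression).

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64; identical seeds and parameters give bit-identical output for a fixed
``GENERATOR_VERSION``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Bumped whenever any sampling routine changes, so that "same seed, same
#: output" is a meaningful reproducibility contract.
GENERATOR_VERSION = "1.0"

# Enumerating all C(n,3) triples is only sensible at desk scale.
_MAX_ENUMERATED_TRIPLES = 20_000_000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEmbedding:
    """Non-negative object x dimension weight matrix with known sparsity.

    Mimics the structure of a sparse positive similarity embedding: entries
    are exactly zero with probability ``sparsity`` and otherwise drawn from a
    right-skewed non-negative distribution.
    """

    weights: np.ndarray
    object_ids: list[str]
    sparsity: float
    seed: int
    generator_version: str = GENERATOR_VERSION

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if len(self.object_ids) != self.weights.shape[0]:
            raise ValueError("object_ids must match the number of rows")

    @property
    def n_objects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_dims(self) -> int:
        return self.weights.shape[1]


@dataclass
class TripletDataset:
    """Triplet odd-one-out trials: three object indices plus the chosen one.

    ``trials`` is an integer array of shape (n_trials, 4) with columns
    ``a, b, c, choice``; the choice is the object judged most dissimilar.
    """

    trials: np.ndarray
    n_objects: int

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.int64)
        if self.trials.ndim != 2 or self.trials.shape[1] != 4:
            raise ValueError("trials must have shape (n_trials, 4)")
        abc = self.trials[:, :3]
        if abc.size and (abc.min() < 0 or abc.max() >= self.n_objects):
            raise ValueError("object indices out of range")
        if np.any(
            (abc[:, 0] == abc[:, 1])
            | (abc[:, 0] == abc[:, 2])
            | (abc[:, 1] == abc[:, 2])
        ):
            raise ValueError("triplet members must be pairwise distinct")
        choice = self.trials[:, 3]
        if np.any(~np.any(abc == choice[:, None], axis=1)):
            raise ValueError("choice must be one of the triplet members")

    def __len__(self) -> int:
        return self.trials.shape[0]

    @property
    def triples(self) -> np.ndarray:
        return self.trials[:, :3]

    @property
    def choices(self) -> np.ndarray:
        return self.trials[:, 3]

    def subset(self, index: np.ndarray) -> "TripletDataset":
        return TripletDataset(self.trials[index], self.n_objects)


@dataclass
class RepeatedMeasures:
    """Repeated responses to identical stimuli: channels x images x repeats."""

    responses: np.ndarray
    channel_ids: list[str]
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be channels x images x repeats")
        if self.responses.shape[2] < 2:
            raise ValueError("need at least 2 repeats per image")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must not contain missing values")

    @property
    def n_channels(self) -> int:
        return self.responses.shape[0]

    @property
    def n_images(self) -> int:
        return self.responses.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[2]


@dataclass
class FusionDataset:
    """Trial-wise sensor time series paired with scalar region responses.

    ``sensor_data`` has shape (n_trials, n_sensors, n_timepoints);
    ``roi_responses`` maps each region name to a length-n_trials vector;
    ``session_labels`` assigns each trial to a recording session (the
    cross-validation unit); ``time_axis`` is in milliseconds with 0 at
    stimulus onset and ``baseline_window`` a pre-stimulus interval.
    """

    sensor_data: np.ndarray
    roi_responses: dict[str, np.ndarray]
    session_labels: np.ndarray
    time_axis: np.ndarray
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.sensor_data = np.asarray(self.sensor_data, dtype=float)
        self.session_labels = np.asarray(self.session_labels, dtype=np.int64)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.sensor_data.ndim != 3:
            raise ValueError("sensor_data must be trials x sensors x timepoints")
        n_trials = self.sensor_data.shape[0]
        if self.session_labels.shape != (n_trials,):
            raise ValueError("session_labels must have one entry per trial")
        _, counts = np.unique(self.session_labels, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every session must contain at least 2 trials")
        if self.time_axis.shape != (self.sensor_data.shape[2],):
            raise ValueError("time_axis must match the sensor time dimension")
        t0, t1 = self.baseline_window
        if not (self.time_axis[0] <= t0 < t1 <= self.time_axis[-1]):
            raise ValueError("baseline_window must lie within the time axis")
        if t1 > 0:
            raise ValueError("baseline_window must precede stimulus onset (0 ms)")
        for name, resp in self.roi_responses.items():
            resp = np.asarray(resp, dtype=float)
            if resp.shape != (n_trials,):
                raise ValueError(f"roi '{name}' must have one response per trial")
            self.roi_responses[name] = resp

    @property
    def n_trials(self) -> int:
        return self.sensor_data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.sensor_data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.sensor_data.shape[2]


@dataclass
class CoverageStats:
    """How often each unordered object pair occurs across a triplet design."""

    mean: float
    min: int | None
    max: int | None
    n_trials: int
    n_pairs: int
    counts: dict[tuple[int, int], int] | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_triplets(n_objects: int) -> int:
    """Exact number of unordered object triples, C(n, 3)."""
    if n_objects < 3:
        raise ValueError("need at least 3 objects to form a triple")
    return math.comb(n_objects, 3)


def count_pairs(n_objects: int) -> int:
    """Exact number of unordered object pairs, C(n, 2)."""
    if n_objects < 2:
        raise ValueError("need at least 2 objects to form a pair")
    return math.comb(n_objects, 2)


def pair_coverage_stats(triples_or_count, n_objects: int) -> CoverageStats:
    """Summarize pair-sampling coverage of a triplet design.

    Each triplet contributes its three unordered pairs. The mean coverage is
    ``3 * n_trials / C(n_objects, 2)`` and can be computed from the trial
    count alone; min and max require the actual triples (pairs that never
    occur count as 0).
    """
    if n_objects < 2:
        raise ValueError("need at least 2 objects")
    n_pairs = count_pairs(n_objects)
    if np.isscalar(triples_or_count):
        n_trials = int(triples_or_count)
        if n_trials < 0:
            raise ValueError("trial count must be non-negative")
        return CoverageStats(
            mean=3.0 * n_trials / n_pairs,
            min=None,
            max=None,
            n_trials=n_trials,
            n_pairs=n_pairs,
        )
    triples = np.asarray(triples_or_count, dtype=np.int64)
    if triples.ndim != 2 or triples.shape[1] < 3:
        raise ValueError("triples must be an (n_trials, 3) array")
    triples = triples[:, :3]
    if triples.size and (triples.min() < 0 or triples.max() >= n_objects):
        raise ValueError("object indices out of range")
    n_trials = triples.shape[0]
    counts: dict[tuple[int, int], int] = {}
    for a, b, c in triples:
        for i, j in ((a, b), (a, c), (b, c)):
            key = (int(min(i, j)), int(max(i, j)))
            counts[key] = counts.get(key, 0) + 1
    observed = list(counts.values())
    cov_min = 0 if len(counts) < n_pairs else min(observed)
    cov_max = max(observed) if observed else 0
    return CoverageStats(
        mean=3.0 * n_trials / n_pairs,
        min=cov_min,
        max=cov_max,
        n_trials=n_trials,
        n_pairs=n_pairs,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_ground_truth_embedding(
    n_objects: int,
    n_dims: int,
    sparsity: float = 0.6,
    scale: float = 1.0,
    seed: int = 0,
) -> GroundTruthEmbedding:
    """Draw a sparse non-negative ground-truth embedding.

    Each entry is exactly zero with probability ``sparsity`` and otherwise
    exponentially distributed with mean ``scale`` — a right-skewed,
    non-negative law matching the qualitative shape of fitted sparse
    positive embedding weights.
    """
    if n_objects < 3:
        raise ValueError("n_objects must be >= 3")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    nonzero = rng.random((n_objects, n_dims)) >= sparsity
    magnitudes = rng.exponential(scale, size=(n_objects, n_dims))
    weights = np.where(nonzero, magnitudes, 0.0)
    object_ids = [f"object_{i:04d}" for i in range(n_objects)]
    return GroundTruthEmbedding(weights, object_ids, sparsity, seed)


def sample_triplet_tasks(
    n_objects: int,
    n_trials: int,
    seed: int = 0,
    balanced: bool = False,
) -> np.ndarray:
    """Sample triplet tasks (three distinct object indices per trial).

    With ``balanced=True`` the design is a shuffled enumeration of all
    C(n, 3) triples, refilled cyclically (reshuffling each pass) when
    ``n_trials`` exceeds the number of distinct triples; complete passes
    cover every pair exactly ``n_objects - 2`` times, so pair coverage stays
    near-uniform. With ``balanced=False`` triples are sampled independently
    and uniformly.
    """
    if n_objects < 3:
        raise ValueError("n_objects must be >= 3")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if balanced:
        n_all = count_triplets(n_objects)
        if n_all > _MAX_ENUMERATED_TRIPLES:
            raise ValueError(
                "balanced design enumerates all C(n,3) triples; "
                f"{n_all} is too many — use balanced=False"
            )
        all_triples = np.array(
            list(itertools.combinations(range(n_objects), 3)), dtype=np.int64
        )
        blocks = []
        remaining = n_trials
        while remaining > 0:
            order = rng.permutation(n_all)
            take = min(remaining, n_all)
            blocks.append(all_triples[order[:take]])
            remaining -= take
        return np.concatenate(blocks, axis=0)
    # independent uniform triples: redraw rows until all members distinct
    out = np.empty((n_trials, 3), dtype=np.int64)
    pending = np.arange(n_trials)
    while pending.size:
        draw = rng.integers(0, n_objects, size=(pending.size, 3))
        ok = (
            (draw[:, 0] != draw[:, 1])
            & (draw[:, 0] != draw[:, 2])
            & (draw[:, 1] != draw[:, 2])
        )
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def _pair_scores(weights: np.ndarray, triples: np.ndarray):
    """Dot-product scores (s_bc, s_ac, s_ab) for each triple.

    Ordered so that column m is the score of the pair *excluding* member m;
    the softmax over these columns gives the probability that member m is
    the odd-one-out.
    """
    xa = weights[triples[:, 0]]
    xb = weights[triples[:, 1]]
    xc = weights[triples[:, 2]]
    s_ab = np.einsum("ij,ij->i", xa, xb)
    s_ac = np.einsum("ij,ij->i", xa, xc)
    s_bc = np.einsum("ij,ij->i", xb, xc)
    return np.stack([s_bc, s_ac, s_ab], axis=1)


def odd_one_out_probabilities(
    weights: np.ndarray, triples: np.ndarray
) -> np.ndarray:
    """P(member m of each triple is the odd-one-out) under the softmax model.

    For a triple (a, b, c), the probability that c is the odd-one-out is
    ``exp(a.b) / (exp(a.b) + exp(a.c) + exp(b.c))`` and cyclically: the pair
    with the largest dot product is the implied most-similar pair, leaving
    the third object as the odd one out.
    """
    triples = np.asarray(triples, dtype=np.int64)
    scores = _pair_scores(np.asarray(weights, dtype=float), triples)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def simulate_choices(
    gt: GroundTruthEmbedding,
    triples: np.ndarray,
    seed: int = 0,
    deterministic: bool = False,
) -> TripletDataset:
    """Run the softmax choice model forward over a list of triples.

    Sampled choices draw the odd-one-out from the three softmax
    probabilities; ``deterministic=True`` picks the argmax-probability
    outcome, breaking ties toward the lowest object index.
    """
    triples = np.asarray(triples, dtype=np.int64)
    if triples.ndim != 2 or triples.shape[1] != 3:
        raise ValueError("triples must have shape (n_trials, 3)")
    if triples.size and (triples.min() < 0 or triples.max() >= gt.n_objects):
        raise ValueError("object indices out of range for the embedding")
    probs = odd_one_out_probabilities(gt.weights, triples)
    if deterministic:
        positions = _argmax_lowest_object(probs, triples)
    else:
        rng = np.random.default_rng(seed)
        u = rng.random(triples.shape[0])
        cdf = np.cumsum(probs, axis=1)
        positions = (u[:, None] >= cdf).sum(axis=1)
        positions = np.minimum(positions, 2)
    choices = triples[np.arange(triples.shape[0]), positions]
    trials = np.concatenate([triples, choices[:, None]], axis=1)
    return TripletDataset(trials, gt.n_objects)


def _argmax_lowest_object(probs: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Position of the max-probability member, ties -> lowest object index."""
    near = probs >= probs.max(axis=1, keepdims=True) - 1e-12
    masked = np.where(near, triples, np.iinfo(np.int64).max)
    winner = masked.min(axis=1)
    return np.argmax(triples == winner[:, None], axis=1)


def simulate_repeated_measures(
    n_channels: int,
    n_images: int,
    n_repeats: int,
    signal_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> RepeatedMeasures:
    """Gaussian signal-plus-noise repeated responses.

    ``response[c, i, r] = mu[c, i] + eps[c, i, r]`` with the per
    channel-image signal ``mu ~ N(0, signal_sd^2)`` and i.i.d. trial noise
    ``eps ~ N(0, noise_sd^2)``. The analytic noise ceiling after averaging n
    repeats is ``signal_sd^2 / (signal_sd^2 + noise_sd^2 / n)``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if signal_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, signal_sd, size=(n_channels, n_images))
    eps = rng.normal(0.0, noise_sd, size=(n_channels, n_images, n_repeats))
    responses = mu[:, :, None] + eps
    return RepeatedMeasures(
        responses,
        channel_ids=[f"channel_{i:04d}" for i in range(n_channels)],
        image_ids=[f"image_{i:04d}" for i in range(n_images)],
    )


def simulate_fusion_data(
    n_trials: int,
    n_sensors: int,
    time_axis: np.ndarray,
    n_sessions: int,
    roi_onsets: dict[str, float],
    snr: float = 1.0,
    roi_noise_sd: float = 0.5,
    seed: int = 0,
    baseline_window: tuple[float, float] | None = None,
) -> FusionDataset:
    """Sensor time series whose region information appears at known latencies.

    Each region of interest has one latent scalar feature per trial
    (standard normal). The region response is that feature plus independent
    Gaussian noise (sd ``roi_noise_sd``). Sensors carry a fixed random
    linear image of each region's feature, scaled by ``snr``, only at
    timepoints at or after that region's onset, on top of unit-variance
    i.i.d. sensor noise — so before all onsets the sensors are pure noise.
    Sessions are contiguous near-equal blocks of trials.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if roi_noise_sd < 0:
        raise ValueError("roi_noise_sd must be non-negative")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    time_axis = np.asarray(time_axis, dtype=float)
    for name, onset in roi_onsets.items():
        if not (time_axis[0] <= onset <= time_axis[-1]):
            raise ValueError(f"onset for roi '{name}' lies outside the time axis")
    if baseline_window is None:
        baseline_window = (float(time_axis[0]), 0.0)
    rng = np.random.default_rng(seed)
    sensor_data = rng.normal(0.0, 1.0, size=(n_trials, n_sensors, time_axis.size))
    roi_responses: dict[str, np.ndarray] = {}
    for name in sorted(roi_onsets):
        feature = rng.normal(0.0, 1.0, size=n_trials)
        pattern = rng.normal(0.0, 1.0, size=n_sensors)
        pattern /= np.linalg.norm(pattern)
        active = time_axis >= roi_onsets[name]
        sensor_data += (
            snr * feature[:, None, None] * pattern[None, :, None] * active[None, None, :]
        )
        roi_responses[name] = feature + rng.normal(0.0, roi_noise_sd, size=n_trials)
    session_labels = (np.arange(n_trials) * n_sessions) // n_trials
    return FusionDataset(
        sensor_data=sensor_data,
        roi_responses=roi_responses,
        session_labels=session_labels,
        time_axis=time_axis,
        baseline_window=baseline_window,
    )
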