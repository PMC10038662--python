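"""Noise ceilings for repeated neuroimaging measurements and repeated triplets.

Two distinct reliability estimates:

* **Explainable-variance ceiling** (fMRI voxels, MEG sensor/timepoints):
  decompose the variance of responses to repeatedly presented images into
  signal and noise, and report the fraction of the total that a perfect
  model could explain, optionally adjusted for averaging over n repeats.

* **Choice-consistency ceiling** (behavior): for triplets judged repeatedly,
  the modal choice's share of the repeats, averaged over triplets, in
  percent. This slightly overestimates the true ceiling because it is
  always based on the most consistent choice observed in the sample; the
  caveat travels with the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RepeatedMeasures

#: Caveat propagated into output metadata wherever the behavioral ceiling is
#: reported: the sample modal share is an upward-biased estimate.
BEHAVIORAL_CEILING_CAVEAT = (
    "consistency ceilings based on the sample modal choice slightly "
    "overestimate the true noise ceiling"
)


@dataclass
class NoiseCeilingEstimate:
    """Signal/noise variance decomposition for one measurement channel.

    ``ceiling = signal_var / (signal_var + noise_var / n_average)``: the
    explainable fraction of the variance of responses averaged over
    ``n_average`` trial repeats. Non-decreasing in ``n_average``.
    """

    signal_var: float
    noise_var: float
    n_average: int
    ceiling: float


@dataclass
class TripletConsistencySet:
    """Per-triplet 3-way choice counts across repeated presentations."""

    per_triplet_counts: np.ndarray

    def __post_init__(self) -> None:
        self.per_triplet_counts = np.asarray(self.per_triplet_counts, dtype=np.int64)
        if self.per_triplet_counts.ndim != 2 or self.per_triplet_counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_triplets, 3)")
        if np.any(self.per_triplet_counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.per_triplet_counts.sum(axis=1) < 2):
            raise ValueError("every triplet must be repeated at least twice")

    @property
    def n_triplets(self) -> int:
        return self.per_triplet_counts.shape[0]


def neuro_noise_ceiling(
    data: RepeatedMeasures,
    n_average: int = 1,
    bias_correct: bool = False,
) -> list[NoiseCeilingEstimate]:
    """Explainable-variance noise ceiling per channel.

    Noise variance is the pooled (mean over images) unbiased variance across
    repeats of the same image; signal variance is the unbiased variance of
    the image-wise mean responses. With ``bias_correct=True`` the signal
    variance is corrected for the residual noise left in the image means,
    ``max(signal_var − noise_var / n_repeats, 0)`` — the uncorrected form
    mirrors the common verbatim recipe and overestimates slightly.
    """
    if n_average < 1:
        raise ValueError("n_average must be >= 1")
    resp = data.responses
    if resp.shape[2] < 2:
        raise ValueError("need at least 2 repeats")
    noise_var = resp.var(axis=2, ddof=1).mean(axis=1)  # pooled over images
    means = resp.mean(axis=2)
    signal_var = means.var(axis=1, ddof=1)
    if bias_correct:
        signal_var = np.maximum(signal_var - noise_var / resp.shape[2], 0.0)
    out = []
    for s, n in zip(signal_var, noise_var):
        denom = s + n / n_average
        ceiling = float(s / denom) if denom > 0 else 0.0
        out.append(NoiseCeilingEstimate(float(s), float(n), n_average, ceiling))
    return out


def behavioral_noise_ceiling(counts: TripletConsistencySet) -> float:
    """Mean per-triplet choice consistency, in percent.

    Consistency of one triplet = 100 · (modal choice count) / (repeats).
    """
    if counts.n_triplets == 0:
        raise ValueError("need at least one repeated triplet")
    c = counts.per_triplet_counts
    consistency = 100.0 * c.max(axis=1) / c.sum(axis=1)
    return float(consistency.mean())


def expected_modal_fraction(probs, n_repeats: int) -> float:
    """Exact E[modal count / n] for a trinomial with the given probabilities.

    Closed-form expectation of the sample modal fraction by enumerating all
    compositions of ``n_repeats`` into three counts — the population value
    the behavioral ceiling converges to under a known choice distribution.
    """
    from math import comb

    p = np.asarray(probs, dtype=float)
    if p.shape != (3,) or abs(p.sum() - 1) > 1e-9 or np.any(p < 0):
        raise ValueError("probs must be a 3-way probability vector")
    total = 0.0
    for k1 in range(n_repeats + 1):
        for k2 in range(n_repeats + 1 - k1):
            k3 = n_repeats - k1 - k2
            pmf = (
                comb(n_repeats, k1)
                * comb(n_repeats - k1, k2)
                * p[0] ** k1
                * p[1] ** k2
                * p[2] ** k3
            )
            total += pmf * max(k1, k2, k3) / n_repeats
    return total


def fraction_to_percent(x: float) -> float:
    return 100.0 * x


def percent_to_fraction(x: float) -> float:
    return x / 100.0
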