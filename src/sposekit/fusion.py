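"""Time-resolved regression from sensor patterns to region responses.

For every timepoint separately, an ordinary-least-squares model maps the
sensor pattern of each trial to a scalar region-of-interest response, under
leave-one-session-out cross-validation (sessions are the exchangeable
acquisition unit). The Pearson correlation between predicted and true
responses on the held-out session, averaged over folds and lightly smoothed
over time, traces when the region's stimulus information becomes available
in the sensors. Onsets are read off as the largest contiguous window whose
correlation exceeds the maximum observed during the pre-stimulus baseline;
confidence bands and region contrasts come from resampling fold-wise
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import FusionDataset


@dataclass
class CorrelationTimeSeries:
    """Held-out prediction accuracy (Pearson r) over time, per fold.

    ``r_per_fold`` may contain NaN where a fold's correlation was undefined
    (constant held-out truth); such folds are excluded from means and
    bootstraps. ``r_mean`` is the across-fold mean smoothed with a centered
    moving average of ``smoothing_window`` timepoints (edge-truncated).
    """

    time_ms: np.ndarray
    r_per_fold: np.ndarray
    r_mean: np.ndarray
    smoothing_window: int

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.r_per_fold = np.asarray(self.r_per_fold, dtype=float)
        self.r_mean = np.asarray(self.r_mean, dtype=float)
        finite = self.r_per_fold[np.isfinite(self.r_per_fold)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.r_mean.shape != self.time_ms.shape:
            raise ValueError("r_mean must match the time axis")

    @property
    def n_folds(self) -> int:
        return self.r_per_fold.shape[0]


@dataclass
class WindowResult:
    """Largest contiguous supra-threshold run of timepoints."""

    threshold: float
    onset_ms: float | None
    offset_ms: float | None
    member_timepoints: np.ndarray

    @property
    def empty(self) -> bool:
        return self.member_timepoints.size == 0


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges.

    Interior points average exactly ``window`` neighbours; near the edges
    the window shrinks to what is available, so the series keeps its length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for t in range(x.size):
        lo = max(0, t - half)
        hi = min(x.size, t + window - half)
        seg = x[lo:hi]
        out[t] = np.nanmean(seg) if np.any(np.isfinite(seg)) else np.nan
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def fit_fusion(
    data: FusionDataset,
    roi: str,
    smoothing_window: int = 5,
) -> CorrelationTimeSeries:
    """Leave-one-session-out OLS from sensors to one region's response.

    Per held-out session and timepoint: fit ordinary least squares (with
    intercept) from the training sessions' sensor patterns to the region
    response, predict the held-out trials, and correlate predictions with
    the true responses. When a fold has fewer training trials than sensors
    the minimum-norm least-squares solution is used (with a warning). Folds
    with constant held-out truth yield an undefined correlation, recorded
    as missing.
    """
    if roi not in data.roi_responses:
        raise ValueError(f"roi '{roi}' not in dataset ({sorted(data.roi_responses)})")
    sessions = np.unique(data.session_labels)
    if sessions.size < 2:
        raise ValueError("need at least 2 sessions for leave-one-session-out")
    y = data.roi_responses[roi]
    n_t = data.n_timepoints
    r = np.full((sessions.size, n_t), np.nan)
    for f, sess in enumerate(sessions):
        test = data.session_labels == sess
        train = ~test
        if train.sum() < data.n_sensors + 1:
            warnings.warn(
                f"fold {f}: {int(train.sum())} training trials for "
                f"{data.n_sensors} sensors; using minimum-norm least squares",
                stacklevel=2,
            )
        y_train, y_test = y[train], y[test]
        if np.ptp(y_test) == 0:
            warnings.warn(f"fold {f}: constant held-out truth; r undefined",
                          stacklevel=2)
            continue
        X_train_all = data.sensor_data[train]
        X_test_all = data.sensor_data[test]
        ones_train = np.ones((int(train.sum()), 1))
        ones_test = np.ones((int(test.sum()), 1))
        for t in range(n_t):
            X = np.hstack([ones_train, X_train_all[:, :, t]])
            beta, *_ = np.linalg.lstsq(X, y_train, rcond=None)
            pred = np.hstack([ones_test, X_test_all[:, :, t]]) @ beta
            r[f, t] = _pearson(pred, y_test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fold_mean = np.nanmean(r, axis=0)
    r_mean = moving_average(fold_mean, smoothing_window)
    return CorrelationTimeSeries(data.time_axis, r, r_mean, smoothing_window)


def supra_baseline_window(
    series: CorrelationTimeSeries,
    baseline: tuple[float, float],
) -> WindowResult:
    """Largest contiguous run exceeding the baseline maximum.

    The threshold is the maximum of the smoothed correlation within the
    baseline interval; the result is the longest run of timepoints strictly
    above it (ties broken toward the earliest run). The window may be empty.
    """
    t0, t1 = baseline
    in_base = (series.time_ms >= t0) & (series.time_ms <= t1)
    if not in_base.any():
        raise ValueError("baseline interval contains no timepoints")
    threshold = float(np.nanmax(series.r_mean[in_base]))
    above = series.r_mean > threshold
    best_start, best_len = None, 0
    start = None
    for t, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            if t - start > best_len:
                best_start, best_len = start, t - start
            start = None
    if best_start is None:
        return WindowResult(threshold, None, None, np.empty(0, dtype=int))
    members = np.arange(best_start, best_start + best_len)
    return WindowResult(
        threshold,
        float(series.time_ms[members[0]]),
        float(series.time_ms[members[-1]]),
        members,
    )


def bootstrap_fusion_ci(
    series: CorrelationTimeSeries,
    n_boot: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Percentile 95% band per timepoint from resampled fold correlations.

    Folds are the exchangeable unit: each draw resamples the fold-wise
    correlation values with replacement and averages. Returns an array of
    shape (2, n_timepoints): lower and upper band.
    """
    if series.n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    n_t = series.time_ms.size
    band = np.full((2, n_t), np.nan)
    for t in range(n_t):
        vals = series.r_per_fold[:, t]
        vals = np.sort(vals[np.isfinite(vals)])  # fold order must not matter
        if vals.size == 0:
            warnings.warn(f"timepoint {t}: no valid folds to resample",
                          stacklevel=2)
            continue
        draws = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))].mean(axis=1)
        band[:, t] = np.percentile(draws, [2.5, 97.5])
    return band


def roi_contrast(
    series_a: CorrelationTimeSeries,
    series_b: CorrelationTimeSeries,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold-paired bootstrap of the difference between two region series.

    Per timepoint, the fold-wise differences (same fold of both series) are
    resampled with replacement; a timepoint is significant when the 95%
    percentile interval of the mean difference excludes 0. Returns the mean
    difference series, the (2, n_timepoints) CI band, and the boolean
    significance mask.
    """
    if not np.array_equal(series_a.time_ms, series_b.time_ms):
        raise ValueError("time axes must match")
    if series_a.n_folds != series_b.n_folds:
        raise ValueError("fold structures must match")
    rng = np.random.default_rng(seed)
    diff = series_a.r_per_fold - series_b.r_per_fold
    n_t = series_a.time_ms.size
    mean_diff = np.full(n_t, np.nan)
    band = np.full((2, n_t), np.nan)
    significant = np.zeros(n_t, dtype=bool)
    for t in range(n_t):
        vals = np.sort(diff[np.isfinite(diff[:, t]), t])  # fold-order invariant
        if vals.size == 0:
            continue
        mean_diff[t] = vals.mean()
        draws = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))].mean(axis=1)
        band[:, t] = np.percentile(draws, [2.5, 97.5])
        significant[t] = band[0, t] > 0 or band[1, t] < 0
    return mean_diff, band, significant
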