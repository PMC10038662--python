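"""Saturation of embedding dimensionality with dataset size.

As the number of triplet judgments grows, the number of retained embedding
dimensions rises and saturates. The module fits the exponential-decay law

    dim(x) = a + b * exp(-c * x),    c > 0,

to mean dimensionality as a function of trial count x, extrapolates its
asymptote ``a``, and puts a percentile bootstrap confidence interval on the
asymptote by resampling the replicate dimensionalities at each size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass
class DimCurve:
    """Retained dimensionality at each dataset size, with replicates.

    ``dims_per_replicate`` has shape (n_sizes, n_replicates): independent
    embedding fits at the same trial count.
    """

    sizes: np.ndarray
    dims_per_replicate: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.dims_per_replicate = np.asarray(self.dims_per_replicate, dtype=float)
        if self.sizes.ndim != 1:
            raise ValueError("sizes must be 1-D")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if self.dims_per_replicate.shape[0] != self.sizes.size:
            raise ValueError("one row of replicate dims per size")
        if np.any(self.dims_per_replicate <= 0):
            raise ValueError("dimensionalities must be positive")

    @property
    def mean_dims(self) -> np.ndarray:
        return self.dims_per_replicate.mean(axis=1)


@dataclass
class ExpDecayFit:
    """Parameters of a + b·e^(−c·x); the asymptote as x → ∞ is ``a``."""

    a: float
    b: float
    c: float
    residual_ss: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("rate c must be positive")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


def predict_dim(fit: ExpDecayFit, size) -> np.ndarray | float:
    """Evaluate a + b·e^(−c·x) at the given trial count(s)."""
    size = np.asarray(size, dtype=float)
    if np.any(size < 0):
        raise ValueError("size must be non-negative")
    out = fit.a + fit.b * np.exp(-fit.c * size)
    return float(out) if out.ndim == 0 else out


def fit_exp_decay(sizes, mean_dims, start=None) -> ExpDecayFit:
    """Nonlinear least squares for the saturation curve.

    Runs from several starting points (the data give no unique convex
    parameterization) and keeps the fit with the lowest residual sum of
    squares; ``c`` is constrained positive via box bounds. ``start`` adds a
    caller-supplied warm start (used by the bootstrap, whose resampled
    curves sit near the observed fit).
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(mean_dims, dtype=float)
    if x.size < 4 or np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct sizes")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("sizes and dims must be finite")
    if np.ptp(y) < 1e-12:
        raise FitError("dimensionality is constant across sizes; b unidentifiable")

    x_range = float(np.ptp(x))
    y_first, y_last = float(y[0]), float(y[-1])
    if start is not None:
        starts = [tuple(start)]
    else:
        starts = []
        for a0 in (y_last, y_last + (y_last - y_first) / 4):
            for c0 in (1.0 / x_range, 5.0 / x_range):
                starts.append((a0, y_first - a0, c0))

    def residuals(theta):
        a, b, c = theta
        return a + b * np.exp(-c * x) - y

    best = None
    diagnostics = []
    for theta0 in starts:
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=([-np.inf, -np.inf, 1e-300], [np.inf, np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            diagnostics.append(f"start {theta0}: {exc}")
            continue
        if not res.success and not np.all(np.isfinite(res.x)):
            diagnostics.append(f"start {theta0}: {res.message}")
            continue
        ss = float(np.sum(res.fun**2))
        if best is None or ss < best[0]:
            best = (ss, res.x)
    if best is None:
        raise FitError("all starts failed: " + "; ".join(diagnostics))
    ss, (a, b, c) = best
    return ExpDecayFit(float(a), float(b), float(c), ss)


def bootstrap_asymptote(
    curve: DimCurve,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float, np.ndarray]:
    """Percentile bootstrap CI for the asymptotic dimensionality.

    Each draw resamples, at every size, the replicate dimensionalities with
    replacement, takes their mean, and refits the decay curve; the 95% CI is
    the (2.5, 97.5) percentile interval of the bootstrap asymptotes. The
    point estimate comes from the fit to the observed means. Draws whose
    refit fails are skipped (with a warning); more than 10% failures is an
    error.
    """
    if curve.dims_per_replicate.shape[1] < 2:
        raise ValueError("need >= 2 replicates per size to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    fit = fit_exp_decay(curve.sizes, curve.mean_dims)
    n_sizes, n_rep = curve.dims_per_replicate.shape
    samples = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_rep, size=(n_sizes, n_rep))
        means = np.take_along_axis(curve.dims_per_replicate, idx, axis=1).mean(axis=1)
        try:
            samples.append(
                fit_exp_decay(curve.sizes, means, start=(fit.a, fit.b, fit.c)).a
            )
        except FitError:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap fits failed and were skipped",
                      stacklevel=2)
    if n_failed > 0.1 * n_boot:
        raise FitError(f"too many bootstrap fit failures ({n_failed}/{n_boot})")
    boot = np.asarray(samples)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    return fit.a, float(ci_low), float(ci_high), boot
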