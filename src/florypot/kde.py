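"""Empirical end-to-end distance densities via Gaussian kernel density estimation.

The empirical density of a sample {r_s} with bandwidth w is

    E(R, w) = (1/M) sum_s N(R; r_s, w),

a Gaussian kernel on the real line with no boundary correction at R = 0
(the distances involved are several Å with w << R, so leaked mass below
zero is negligible and is monitored by the normalization tests).

Bandwidths are chosen by 5-fold cross-validation: each fold is held out
once, the KDE is built on the remaining four, and the w maximizing the
summed held-out log-likelihood wins.  Because CV is expensive, it is run at
a handful of separations and the power law w = a * n**s is then fitted to
predict bandwidths for all other sample sizes.

Numerics: the kernel sum is evaluated exactly (chunked log-sum-exp) for
small samples; for large samples a fine-grid binned convolution
(scipy.ndimage.gaussian_filter1d, bin width <= w/8) is used, whose relative
error O((bin/w)^2 / 24) is far below every tolerance used in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .errors import DomainError, InsufficientDataError, UnderdeterminedFitError
from .fragments import FragmentSet
from .io_structures import CoarseGrainLevel

#: Default bandwidth search grid: 40 log-spaced values spanning 0.01-10 Å.
DEFAULT_W_GRID = np.geomspace(0.01, 10.0, 40)

_EXACT_PAIR_LIMIT = 2.0e6   # switch to binned evaluation above this many pairs
_TINY = 1e-300


@dataclass(eq=False)
class EmpiricalDensity:
    """KDE of an end-to-end distance sample, evaluated on a grid."""

    m: int
    w: float
    n: int
    grid: np.ndarray
    density: np.ndarray
    level: CoarseGrainLevel | None = None
    sample: np.ndarray | None = field(default=None, repr=False)

    def evaluate(self, r) -> np.ndarray:
        """Exact/binned KDE evaluation at arbitrary points (needs the sample)."""
        if self.sample is None:
            raise DomainError("density was built without retaining the sample")
        return np.exp(kde_log_density(self.sample, np.asarray(r, float), self.w))


def kde_log_density(sample, query, w: float) -> np.ndarray:
    """log E(query) for a Gaussian KDE with bandwidth w."""
    x = np.asarray(sample, dtype=float).ravel()
    q = np.asarray(query, dtype=float).ravel()
    if w <= 0:
        raise DomainError("bandwidth must be > 0")
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    if x.size * q.size <= _EXACT_PAIR_LIMIT:
        return _exact_log_density(x, q, w)
    return _binned_log_density(x, q, w)


def _exact_log_density(x: np.ndarray, q: np.ndarray, w: float) -> np.ndarray:
    const = -np.log(x.size) - 0.5 * np.log(2.0 * np.pi) - np.log(w)
    out = np.empty(q.size)
    block = max(1, int(_EXACT_PAIR_LIMIT // max(x.size, 1)))
    for s in range(0, q.size, block):
        z = -0.5 * ((q[s : s + block, None] - x[None, :]) / w) ** 2
        out[s : s + block] = logsumexp(z, axis=1) + const
    return out


def _binned_log_density(x: np.ndarray, q: np.ndarray, w: float) -> np.ndarray:
    lo = min(x.min(), q.min()) - 8.0 * w
    hi = max(x.max(), q.max()) + 8.0 * w
    nbins = int(np.clip(np.ceil((hi - lo) / (w / 8.0)), 256, 2**21))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    dx = edges[1] - edges[0]
    dens = gaussian_filter1d(
        counts.astype(float), sigma=w / dx, mode="constant", truncate=9.0
    ) / (x.size * dx)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = np.interp(q, centers, dens)
    return np.log(np.maximum(f, _TINY))


def _heldout_loglik(train: np.ndarray, test: np.ndarray, w: float) -> float:
    return float(np.sum(kde_log_density(train, test, w)))


def cross_validate_bandwidth(
    fs: FragmentSet | np.ndarray,
    n_folds: int = 5,
    w_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> float:
    """Bandwidth maximizing the summed held-out log-likelihood over k folds.

    Fold assignment is a seeded random permutation; a degenerate sample
    (all values identical) returns the smallest grid bandwidth with a
    warning.
    """
    x = fs.distances if isinstance(fs, FragmentSet) else np.asarray(fs, float)
    x = x.ravel()
    w_grid = DEFAULT_W_GRID if w_grid is None else np.asarray(w_grid, float)
    if len(w_grid) == 0 or np.any(w_grid <= 0) or np.any(np.diff(w_grid) < 0):
        raise DomainError("w_grid must be positive and sorted ascending")
    if len(w_grid) == 1:
        return float(w_grid[0])
    if x.size < 2 * n_folds:
        raise InsufficientDataError(
            f"CV needs >= {2 * n_folds} samples, got {x.size}"
        )
    if np.ptp(x) == 0:
        warnings.warn("degenerate sample (all values equal); returning smallest w")
        return float(w_grid[0])
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(x.size), n_folds)
    scores = np.zeros(len(w_grid))
    for k in range(n_folds):
        test_idx = folds[k]
        train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        train, test = x[train_idx], x[test_idx]
        for iw, w in enumerate(w_grid):
            scores[iw] += _heldout_loglik(train, test, w)
    return float(w_grid[int(np.argmax(scores))])


@dataclass
class BandwidthModel:
    """Power law w = a * n**s linking bandwidth to sample size."""

    a_bw: float
    s_bw: float

    def predict(self, n: int | np.ndarray):
        out = self.a_bw * np.asarray(n, dtype=float) ** self.s_bw
        return float(out) if np.ndim(out) == 0 else out


def fit_bandwidth_scaling(
    points: Sequence[tuple[float, float]], log_space: bool = False
) -> BandwidthModel:
    """Fit (a, s) of w = a * n**s to cross-validated (n, w) points.

    By default the RMSD is minimized in linear w; ``log_space=True`` fits
    log w = log a + s log n by least squares instead.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise UnderdeterminedFitError("need >= 2 (n, w) points")
    n, w = pts[:, 0], pts[:, 1]
    if np.any(n < 1) or np.any(w <= 0):
        raise DomainError("sample sizes must be >= 1 and bandwidths > 0")
    if np.unique(n).size < 2:
        raise UnderdeterminedFitError("need >= 2 distinct sample sizes")
    if np.ptp(w) == 0:
        return BandwidthModel(a_bw=float(w[0]), s_bw=0.0)
    slope, intercept = np.polyfit(np.log(n), np.log(w), 1)
    if log_space:
        return BandwidthModel(a_bw=float(np.exp(intercept)), s_bw=float(slope))
    res = least_squares(
        lambda p: p[0] * n ** p[1] - w,
        x0=[float(np.exp(intercept)), float(slope)],
        method="lm",
    )
    return BandwidthModel(a_bw=float(res.x[0]), s_bw=float(res.x[1]))


def empirical_density(
    fs: FragmentSet | np.ndarray,
    w: float,
    grid: np.ndarray | None = None,
    m: int | None = None,
    level: CoarseGrainLevel | None = None,
) -> EmpiricalDensity:
    """Evaluate the Gaussian KDE of a fragment set on a distance grid."""
    if w <= 0:
        raise DomainError("bandwidth must be > 0")
    if isinstance(fs, FragmentSet):
        x, m, level = fs.distances, fs.m, fs.level
    else:
        x = np.asarray(fs, dtype=float).ravel()
        if m is None:
            raise DomainError("m must be given for a bare sample")
    if x.size < 1:
        raise InsufficientDataError("empty sample")
    if grid is None:
        from .potential import default_grid

        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    dens = np.exp(kde_log_density(x, grid, w))
    return EmpiricalDensity(
        m=int(m), w=float(w), n=int(x.size), grid=grid, density=dens,
        level=level, sample=x,
    )


def density_to_tsv(E: EmpiricalDensity, path) -> None:
    import pandas as pd

    pd.DataFrame({"R": E.grid, "density": E.density}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
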