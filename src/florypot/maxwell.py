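"""Maxwell (ideal-chain) reference distribution and Kuhn-length estimation.

For an ideal (Gaussian) chain, the end-to-end distance R of a fragment of
sequence separation m follows the Maxwell distribution

    M_m(R, b) = 4 pi R^2 (3 / (2 pi b^2 m))^{3/2} exp(-3 R^2 / (2 b^2 m)),

whose single parameter b is the Kuhn length.  The maximum-likelihood
estimator of b has the closed form  b_hat = sqrt(mean(R^2) / m), with the
Fisher-information uncertainty sigma_b = b_hat / sqrt(6 n).

In the Flory regime b(m) plateaus; b* is the unweighted mean of b(m) over
the plateau range (70 <= m <= 90 by default).  The thermal exponent nu is
the slope of log<R> against log m: 1/2 for ideal chains, 1/3 for compact
globules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    IncompleteRangeError,
    InsufficientDataError,
)
from .fragments import FragmentSet
from .io_structures import CoarseGrainLevel


@dataclass
class MaxwellFit:
    m: int
    b: float          # Kuhn length, Å
    sigma_b: float    # Fisher uncertainty b / sqrt(6 n), Å
    n: int
    level: CoarseGrainLevel | None = None


@dataclass
class PlateauEstimate:
    b_star: float
    sigma_b_star: float
    m_range: tuple[int, int]


@dataclass
class ScalingFit:
    nu: float
    intercept: float            # log-space intercept
    fit_m_range: tuple[int, int]
    nu_stderr: float = float("nan")


def maxwell_scale(b: float, m: int) -> float:
    """Scale of the equivalent scipy.stats.maxwell: s = b * sqrt(m/3)."""
    return b * np.sqrt(m / 3.0)


def maxwell_pdf(R, b: float, m: int):
    """Ideal-chain end-to-end distance density M_m(R, b) in 1/Å."""
    R = np.asarray(R, dtype=float)
    if b <= 0:
        raise DomainError("b must be > 0")
    if m < 1:
        raise DomainError("m must be >= 1")
    if np.any(R < 0):
        raise DomainError("R must be >= 0")
    s2 = b * b * m
    out = 4.0 * np.pi * R**2 * (3.0 / (2.0 * np.pi * s2)) ** 1.5 * np.exp(
        -1.5 * R**2 / s2
    )
    return out if out.ndim else float(out)


def maxwell_ppf(q, b: float, m: int):
    """Quantile of M_m(R, b) (via the scipy maxwell distribution)."""
    return stats.maxwell.ppf(q, scale=maxwell_scale(b, m))


def sample_maxwell(m: int, b: float, n: int, rng) -> np.ndarray:
    """Draw n end-to-end distances from M_m(R, b)."""
    rng = np.random.default_rng(rng)
    return stats.maxwell.rvs(scale=maxwell_scale(b, m), size=n, random_state=rng)


def fit_kuhn_length(fs: FragmentSet) -> MaxwellFit:
    """Closed-form maximum-likelihood Kuhn length: b = sqrt(mean(R^2)/m)."""
    if fs.n < 2:
        raise InsufficientDataError(
            f"Kuhn-length fit at m={fs.m} needs n >= 2, got {fs.n}"
        )
    b = float(np.sqrt(np.mean(fs.distances**2) / fs.m))
    return MaxwellFit(
        m=fs.m, b=b, sigma_b=b / np.sqrt(6.0 * fs.n), n=fs.n, level=fs.level
    )


def plateau_kuhn_length(
    fits: Sequence[MaxwellFit], m_range: tuple[int, int] = (70, 90)
) -> PlateauEstimate:
    """Unweighted mean of b(m) over the plateau, with propagated uncertainty."""
    lo, hi = int(m_range[0]), int(m_range[1])
    by_m = {f.m: f for f in fits}
    missing = [m for m in range(lo, hi + 1) if m not in by_m]
    if missing:
        raise IncompleteRangeError(
            f"plateau needs every m in [{lo}, {hi}]; missing {missing}"
        )
    sel = [by_m[m] for m in range(lo, hi + 1)]
    k = len(sel)
    b_star = float(np.mean([f.b for f in sel]))
    sigma = float(np.sqrt(np.sum([f.sigma_b**2 for f in sel])) / k)
    return PlateauEstimate(b_star=b_star, sigma_b_star=sigma, m_range=(lo, hi))


def scaling_exponent(
    mean_R_by_m: Mapping[int, float], fit_m_range: tuple[int, int]
) -> ScalingFit:
    """Least-squares slope of log<R> vs log m over ``fit_m_range``."""
    lo, hi = fit_m_range
    ms = np.array(sorted(m for m in mean_R_by_m if lo <= m <= hi), dtype=float)
    if len(ms) < 3:
        raise InsufficientDataError(
            f"scaling fit needs >= 3 points in [{lo}, {hi}], got {len(ms)}"
        )
    R = np.array([mean_R_by_m[int(m)] for m in ms], dtype=float)
    if np.any(R <= 0):
        raise DomainError("mean distances must be > 0")
    res = stats.linregress(np.log(ms), np.log(R))
    return ScalingFit(
        nu=float(res.slope),
        intercept=float(res.intercept),
        fit_m_range=(int(lo), int(hi)),
        nu_stderr=float(res.stderr),
    )


def fits_to_tsv(fits: Sequence[MaxwellFit], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "level": [f.level.value if f.level else "" for f in fits],
            "m": [f.m for f in fits],
            "n": [f.n for f in fits],
            "b": [f.b for f in fits],
            "sigma_b": [f.sigma_b for f in fits],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
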