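"""Globularity pruning and tangent-vector correlation.

Compact (globular) chains obey R_g = a * N**(1/3).  The dataset filter fits
this power law to all (N, R_g) points by least squares in log space and
discards chains whose log-residual exceeds ``k`` standard deviations
(default k = 3).  The fit-and-discard is a single pass: the prefactor is not
re-fitted after pruning.

The tangent-tangent correlation <cos theta(m)> quantifies local chain
stiffness: secondary-structure elements keep tangents aligned at short
sequence separations, which is why short fragments cannot be treated as
ideal-chain segments.  The tangent at residue i is the central difference
CA(i+1) - CA(i-1); terminal residues have no tangent and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FlorypotError, UnderdeterminedFitError
from .io_structures import Chain


@dataclass
class GlobularityFit:
    """Result of the R_g = a * N**(1/3) fit and 3-sigma pruning."""

    a: float                      # prefactor, Å
    residual_sd: float            # sd of log-residuals (dimensionless)
    retained_ids: list
    discarded_ids: list
    table: pd.DataFrame           # id, N, R_g, log_residual, retained

    def write_report(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class TangentCorrelation:
    separations: np.ndarray   # m values, 0..m_max
    mean_cosine: np.ndarray   # NaN where no pairs observed
    counts: np.ndarray


def fit_globularity(
    points: Sequence[tuple[float, float]],
    ids: Sequence | None = None,
    k: float = 3.0,
) -> GlobularityFit:
    """Fit R_g = a * N**(1/3) and flag chains deviating by more than k sigma.

    ``points`` is a sequence of (N, R_g) pairs; ``ids`` optional parallel
    labels (defaults to 0..len-1).  Residuals are measured in log space, the
    natural space of a power-law fit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise UnderdeterminedFitError(
            f"globularity fit needs >= 3 (N, R_g) points, got {len(pts)}"
        )
    N, rg = pts[:, 0], pts[:, 1]
    if np.any(N < 2):
        raise DomainError("all N must be >= 2")
    if np.any(rg <= 0):
        raise DomainError("all R_g must be > 0")
    if ids is None:
        ids = list(range(len(pts)))
    ids = list(ids)
    if len(ids) != len(pts):
        raise DomainError("ids must parallel points")

    log_resid = np.log(rg) - np.log(N) / 3.0
    log_a = float(np.mean(log_resid))
    resid = log_resid - log_a
    sd = float(np.std(resid))  # population sd; single pruning pass
    discard_mask = np.abs(resid) > k * sd if sd > 0 else np.zeros(len(pts), bool)

    table = pd.DataFrame(
        {
            "id": ids,
            "N": N.astype(int),
            "R_g": rg,
            "log_residual": resid,
            "retained": ~discard_mask,
        }
    )
    return GlobularityFit(
        a=float(np.exp(log_a)),
        residual_sd=sd,
        retained_ids=[i for i, d in zip(ids, discard_mask) if not d],
        discarded_ids=[i for i, d in zip(ids, discard_mask) if d],
        table=table,
    )


def tangent_correlation(chains: Sequence[Chain], m_max: int) -> TangentCorrelation:
    """Average cosine between tangent vectors at sequence separation 0..m_max.

    Chains shorter than 3 residues contribute nothing; residues with a
    missing CA (or a missing neighbour CA) are excluded from the average.
    """
    if not chains:
        raise FlorypotError("tangent_correlation: empty chain ensemble")
    if m_max < 0:
        raise DomainError("m_max must be >= 0")
    sums = np.zeros(m_max + 1)
    counts = np.zeros(m_max + 1, dtype=np.int64)
    for chain in chains:
        X = chain.ca_array()
        if chain.N < 3:
            continue
        T = X[2:] - X[:-2]  # tangent at residues 1..N-2
        norms = np.linalg.norm(T, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            U = T / norms[:, None]
        ok = np.isfinite(norms) & (norms > 0)
        for m in range(0, min(m_max, len(U) - 1) + 1):
            valid = ok[: len(U) - m] & ok[m:]
            if not valid.any():
                continue
            dots = np.einsum("ij,ij->i", U[: len(U) - m][valid], U[m:][valid])
            sums[m] += dots.sum()
            counts[m] += valid.sum()
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # a unit vector's self-cosine is 1 by definition; avoid fp round-off at m=0
    if counts[0] > 0:
        mean[0] = 1.0
    mean = np.clip(mean, -1.0, 1.0)
    return TangentCorrelation(
        separations=np.arange(m_max + 1), mean_cosine=mean, counts=counts
    )
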