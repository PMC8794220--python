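"""Boltzmann inversion against the ideal-chain reference and potential analysis.

The statistical potential at sequence separation m is

    V_m(R | b, w) = -ln( E_m(R, w) / M_m(R, b) )      [units of kB*T, kB*T = 1]

where E_m is the KDE of observed end-to-end distances and M_m the Maxwell
distribution of an ideal chain with the maximum-likelihood Kuhn length.
The R-independent partition-function ratio of the underlying free-energy
difference is dropped, so every potential carries an additive-constant
gauge; comparisons to injected potentials subtract the mean over the
common support.

V_m is defined only where the empirical density is statistically meaningful:
grid points whose implied expected count per grid bin falls below
``min_count`` (default 5) are marked NaN instead of log-of-noise spikes.

The per-m curves are averaged pointwise into V*(R) over the Flory plateau
(70 <= m <= 90) or V-bar(R) over the broad Gaussian range (30 <= m <= 90),
with the across-m standard deviation as the spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal, stats

from .errors import (
    ConsistencyError,
    DomainError,
    FitRangeError,
    IncompleteRangeError,
    InsufficientStatisticsError,
)
from .fragments import FragmentSet, enumerate_buried_fragments
from .io_structures import Chain, CoarseGrainLevel
from .kde import BandwidthModel, EmpiricalDensity, empirical_density
from .maxwell import MaxwellFit, fit_kuhn_length, maxwell_pdf

GRID_MIN = 0.0
GRID_MAX = 30.0
GRID_STEP = 0.1


def default_grid() -> np.ndarray:
    """Shared distance grid: 0 to 30 Å in 0.1 Å steps."""
    n = int(round((GRID_MAX - GRID_MIN) / GRID_STEP)) + 1
    return np.round(np.linspace(GRID_MIN, GRID_MAX, n), 10)


@dataclass(eq=False)
class PotentialCurve:
    """V_m(R) on the shared grid; NaN where the density support fails."""

    m: int
    grid: np.ndarray
    values: np.ndarray
    level: CoarseGrainLevel | None = None


@dataclass(eq=False)
class StatisticalPotential:
    level: CoarseGrainLevel | None
    grid: np.ndarray
    per_m_curves: dict[int, PotentialCurve]
    average: np.ndarray          # NaN outside the common support
    spread: np.ndarray           # population sd across m
    m_range: tuple[int, int]
    kind: str                    # "flory_70_90" or "broad_30_90"
    terminal_pair: tuple[str, str] | None = None
    b_by_m: dict[int, float] = field(default_factory=dict)
    w_by_m: dict[int, float] = field(default_factory=dict)


@dataclass
class PotentialMinima:
    minima: list[tuple[float, float]]   # (position Å, depth kB*T), increasing R


@dataclass
class RepulsionFit:
    exponent: float
    prefactor: float
    fit_range: tuple[float, float]
    exponent_stderr: float = float("nan")


@dataclass
class TotalScore:
    v_tot: float
    contributions: list[tuple[int, int, float, float]]  # (i, j, R_ij, V)
    n_skipped_pairs: int = 0
    n_clamped_pairs: int = 0


def boltzmann_inversion(
    E: EmpiricalDensity, ref: MaxwellFit, min_count: float = 5.0
) -> PotentialCurve:
    """V(R) = -ln(E(R)/M_m(R, b)) where the empirical support is adequate."""
    if E.m != ref.m:
        raise ConsistencyError(f"density m={E.m} but reference m={ref.m}")
    if E.level is not None and ref.level is not None and E.level != ref.level:
        raise ConsistencyError(
            f"density level {E.level} but reference level {ref.level}"
        )
    grid = np.asarray(E.grid, dtype=float)
    steps = np.diff(grid)
    if steps.size == 0 or not np.allclose(steps, steps[0]):
        raise DomainError("boltzmann_inversion expects a uniform grid")
    threshold = min_count / (steps[0] * E.n)
    M = maxwell_pdf(grid, ref.b, ref.m)
    values = np.full_like(grid, np.nan)
    ok = (E.density >= threshold) & (M > 0)
    values[ok] = -np.log(E.density[ok] / M[ok])
    return PotentialCurve(m=E.m, grid=grid, values=values, level=E.level)


def average_potential(
    curves: Mapping[int, PotentialCurve],
    m_range: tuple[int, int] | None = None,
    kind: str = "flory_70_90",
    min_defined_fraction: float = 1.0,
) -> StatisticalPotential:
    """Pointwise mean and spread of per-m curves over ``m_range``.

    A grid point enters the average only where at least
    ``min_defined_fraction`` of the selected curves are defined (default:
    all of them).  The spread is the population standard deviation.
    """
    if m_range is not None:
        lo, hi = int(m_range[0]), int(m_range[1])
        sel = {m: c for m, c in curves.items() if lo <= m <= hi}
    else:
        sel = dict(curves)
        lo, hi = (min(sel), max(sel)) if sel else (0, 0)
    if not sel:
        raise IncompleteRangeError(f"no potential curves in range {m_range}")
    grid = next(iter(sel.values())).grid
    for c in sel.values():
        if c.grid.shape != grid.shape or not np.allclose(c.grid, grid):
            raise ConsistencyError("curves must share the distance grid")
    stack = np.vstack([sel[m].values for m in sorted(sel)])
    defined = np.isfinite(stack)
    frac = defined.mean(axis=0)
    use = frac >= min_defined_fraction - 1e-12
    use &= defined.any(axis=0)
    avg = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    if use.any():
        sub = stack[:, use]
        with np.errstate(invalid="ignore"):
            avg[use] = np.nanmean(sub, axis=0)
            sd[use] = np.nanstd(sub, axis=0)  # ddof=0 by convention
    levels = {c.level for c in sel.values() if c.level is not None}
    return StatisticalPotential(
        level=levels.pop() if len(levels) == 1 else None,
        grid=grid,
        per_m_curves=dict(sel),
        average=avg,
        spread=sd,
        m_range=(lo, hi),
        kind=kind,
    )


def _segments(mask: np.ndarray):
    """Yield (start, stop) slices of contiguous True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def find_minima(
    sp: StatisticalPotential,
    smooth_window: int = 3,
    require_significant: bool = True,
) -> PotentialMinima:
    """Strict local minima of the average curve.

    Candidate minima are located on a lightly smoothed curve (moving average,
    ``smooth_window`` grid points); positions and depths are then refined by
    a parabola through the three raw grid values.  When
    ``require_significant``, a minimum is reported only if its topographic
    prominence is at least the across-m spread at that point, which
    suppresses minima indistinguishable from curve-to-curve noise.
    """
    v = sp.average
    if np.isfinite(v).sum() < 5:
        return PotentialMinima(minima=[])
    out: list[tuple[float, float]] = []
    for start, stop in _segments(np.isfinite(v)):
        seg = v[start:stop]
        if seg.size < 3:
            continue
        s = seg.copy()
        if smooth_window >= 3 and seg.size >= smooth_window:
            half = smooth_window // 2
            kern = np.ones(smooth_window) / smooth_window
            inner = np.convolve(seg, kern, mode="valid")
            s[half : half + inner.size] = inner
        peaks, props = signal.find_peaks(-s, prominence=0.0)
        for p, prom in zip(peaks, props["prominences"]):
            gi = start + p
            if require_significant:
                spread = sp.spread[gi] if np.isfinite(sp.spread[gi]) else 0.0
                if prom < spread:
                    continue
            y0, y1, y2 = v[gi - 1], v[gi], v[gi + 1]
            denom = y0 - 2.0 * y1 + y2
            if np.isfinite(denom) and denom > 0:
                delta = 0.5 * (y0 - y2) / denom
                delta = float(np.clip(delta, -1.0, 1.0))
                pos = sp.grid[gi] + delta * (sp.grid[1] - sp.grid[0])
                depth = y1 - 0.25 * (y0 - y2) * delta
            else:
                pos, depth = sp.grid[gi], y1
            out.append((float(pos), float(depth)))
    out.sort()
    return PotentialMinima(minima=out)


def fit_repulsive_power_law(
    sp: StatisticalPotential,
    fit_range: tuple[float, float] | None = None,
    v_cut: float = 1.0,
) -> RepulsionFit:
    """Power-law fit of the short-range repulsion: ln V linear in ln R.

    The default window runs from the smallest defined grid point to the R
    where the average potential first drops below ``v_cut`` (1 kB*T).
    """
    v, grid = sp.average, sp.grid
    defined = np.isfinite(v) & (grid > 0)
    if not defined.any():
        raise FitRangeError("potential has no defined support")
    if fit_range is None:
        first = int(np.flatnonzero(defined)[0])
        below = np.flatnonzero(defined & (v < v_cut) & (np.arange(v.size) > first))
        last = int(below[0]) if below.size else int(np.flatnonzero(defined)[-1])
        fit_range = (float(grid[first]), float(grid[last]))
    lo, hi = fit_range
    window = defined & (grid >= lo) & (grid <= hi)
    if window.sum() < 3:
        raise FitRangeError(f"fit window [{lo}, {hi}] has < 3 defined points")
    if np.any(v[window] <= 0):
        raise FitRangeError(
            f"potential non-positive inside [{lo}, {hi}]; shrink the upper bound"
        )
    res = stats.linregress(np.log(grid[window]), np.log(v[window]))
    return RepulsionFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        fit_range=(float(lo), float(hi)),
        exponent_stderr=float(res.stderr),
    )


def derive_potentials(
    sets_by_m: Mapping[int, FragmentSet],
    bandwidth: BandwidthModel | Mapping[int, float] | float,
    m_range: tuple[int, int],
    kind: str,
    grid: np.ndarray | None = None,
    min_count: float = 5.0,
    min_samples: int = 2,
) -> StatisticalPotential:
    """Full per-m derivation: Kuhn-length fit, KDE, Boltzmann inversion, average.

    ``bandwidth`` may be a fitted :class:`BandwidthModel` (predicting w from
    the per-m sample size), an explicit m -> w mapping, or one fixed value.
    Separations with fewer than ``min_samples`` fragments are dropped.
    """
    if grid is None:
        grid = default_grid()
    lo, hi = int(m_range[0]), int(m_range[1])
    curves: dict[int, PotentialCurve] = {}
    b_by_m: dict[int, float] = {}
    w_by_m: dict[int, float] = {}
    for m in sorted(sets_by_m):
        if not lo <= m <= hi:
            continue
        fs = sets_by_m[m]
        if fs.n < max(min_samples, 2):
            continue
        ref = fit_kuhn_length(fs)
        if isinstance(bandwidth, BandwidthModel):
            w = bandwidth.predict(fs.n)
        elif isinstance(bandwidth, Mapping):
            if m not in bandwidth:
                continue
            w = float(bandwidth[m])
        else:
            w = float(bandwidth)
        E = empirical_density(fs, w, grid=grid)
        curves[m] = boltzmann_inversion(E, ref, min_count=min_count)
        b_by_m[m] = ref.b
        w_by_m[m] = w
    if not curves:
        raise InsufficientStatisticsError(
            f"no separation in [{lo}, {hi}] had enough fragments"
        )
    sp = average_potential(curves, (lo, hi), kind=kind)
    sp.b_by_m = b_by_m
    sp.w_by_m = w_by_m
    return sp


def derive_sequence_dependent(
    restricted_sets: Mapping[int, FragmentSet],
    bandwidth: BandwidthModel | Mapping[int, float] | float,
    pair: tuple[str, str],
    m_range: tuple[int, int] = (30, 90),
    min_count_per_m: int = 50,
    grid: np.ndarray | None = None,
) -> StatisticalPotential:
    """Sequence-dependent potential from type-restricted fragment sets.

    Both the empirical density and the Maxwell reference are refitted on the
    restricted sets, so the pair potential is self-normalized.  Separations
    with fewer than ``min_count_per_m`` fragments are dropped from the broad
    average.
    """
    try:
        sp = derive_potentials(
            restricted_sets,
            bandwidth,
            m_range,
            kind="broad_30_90",
            grid=grid,
            min_samples=min_count_per_m,
        )
    except InsufficientStatisticsError:
        raise InsufficientStatisticsError(
            f"pair {pair[0]}-{pair[1]}: no separation in {m_range} reached "
            f"{min_count_per_m} fragments"
        ) from None
    sp.terminal_pair = (pair[0], pair[1])
    return sp


def _interp_curve(curve_grid, curve_vals, r):
    """Interpolate over the defined part; clamp outside; flag clamped points."""
    defined = np.isfinite(curve_vals)
    g, v = curve_grid[defined], curve_vals[defined]
    vals = np.interp(r, g, v)
    clamped = (r < g[0]) | (r > g[-1])
    return vals, clamped


def score_structure(
    chain: Chain,
    sp: StatisticalPotential,
    level: CoarseGrainLevel,
) -> TotalScore:
    """Total pairwise score V_tot = sum_{i<j} V_{|j-i|}(R_ij).

    Separations with a per-m curve use it; when the potential carries only
    an average curve it is applied to every separation inside its m range.
    Pairs at unsupported separations are skipped and counted; distances
    outside a curve's defined grid support contribute the nearest boundary
    value and are counted as clamped.
    """
    level = CoarseGrainLevel(level)
    if sp.level is not None and sp.level != level:
        raise ConsistencyError(f"potential level {sp.level} but scoring at {level}")
    from .fragments import end_to_end_distance

    N = chain.N
    contributions: list[tuple[int, int, float, float]] = []
    v_tot = 0.0
    n_skipped = 0
    n_clamped = 0
    use_average = not sp.per_m_curves
    X = chain.ca_array() if level is CoarseGrainLevel.CA else None

    for m in range(1, N):
        if use_average:
            if not sp.m_range[0] <= m <= sp.m_range[1]:
                n_skipped += N - m
                continue
            cg, cv = sp.grid, sp.average
        elif m in sp.per_m_curves:
            c = sp.per_m_curves[m]
            cg, cv = c.grid, c.values
        else:
            n_skipped += N - m
            continue
        if not np.isfinite(cv).any():
            n_skipped += N - m
            continue
        if X is not None:
            d = np.linalg.norm(X[m:] - X[:-m], axis=1)
            idx_i = np.arange(N - m)
        else:
            d = np.array(
                [
                    end_to_end_distance(chain.residues[i], chain.residues[i + m], level)
                    for i in range(N - m)
                ]
            )
            idx_i = np.arange(N - m)
        vals, clamped = _interp_curve(cg, cv, d)
        n_clamped += int(clamped.sum())
        v_tot += float(vals.sum())
        contributions.extend(
            (int(i), int(i + m), float(r), float(vv))
            for i, r, vv in zip(idx_i, d, vals)
        )
    return TotalScore(
        v_tot=v_tot,
        contributions=contributions,
        n_skipped_pairs=n_skipped,
        n_clamped_pairs=n_clamped,
    )


def potential_to_tsv(
    sp: StatisticalPotential,
    path: str | Path,
    sidecar: str | Path | None = None,
    minima: PotentialMinima | None = None,
    repulsion: RepulsionFit | None = None,
) -> None:
    """Write the averaged potential as TSV plus an optional JSON sidecar."""
    import pandas as pd

    stack = (
        np.vstack([c.values for c in sp.per_m_curves.values()])
        if sp.per_m_curves
        else sp.average[None, :]
    )
    n_curves = np.isfinite(stack).sum(axis=0)
    header = (
        f"# level={sp.level.value if sp.level else 'NA'}"
        f" kind={sp.kind} m_range={sp.m_range[0]}-{sp.m_range[1]}"
        f" pair={'-'.join(sp.terminal_pair) if sp.terminal_pair else 'NA'}\n"
        f"# b_by_m={json.dumps({str(k): round(v, 6) for k, v in sp.b_by_m.items()})}\n"
        f"# w_by_m={json.dumps({str(k): round(v, 6) for k, v in sp.w_by_m.items()})}\n"
    )
    df = pd.DataFrame(
        {
            "R": sp.grid,
            "V_mean": sp.average,
            "V_sd": sp.spread,
            "n_curves": n_curves,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    if sidecar is not None:
        payload = {
            "level": sp.level.value if sp.level else None,
            "kind": sp.kind,
            "m_range": list(sp.m_range),
            "terminal_pair": list(sp.terminal_pair) if sp.terminal_pair else None,
            "minima": [list(x) for x in (minima.minima if minima else [])],
            "repulsion": (
                {
                    "exponent": repulsion.exponent,
                    "prefactor": repulsion.prefactor,
                    "fit_range": list(repulsion.fit_range),
                }
                if repulsion
                else None
            ),
        }
        Path(sidecar).write_text(json.dumps(payload, indent=2, sort_keys=True))


def potential_from_tsv(path: str | Path) -> StatisticalPotential:
    """Reload an averaged potential written by :func:`potential_to_tsv`."""
    import pandas as pd

    lines = Path(path).read_text().splitlines()
    meta = {}
    for ln in lines[:3]:
        if ln.startswith("# level="):
            for tok in ln[2:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    lo, hi = (int(x) for x in meta.get("m_range", "0-0").split("-"))
    pair = meta.get("pair", "NA")
    return StatisticalPotential(
        level=(
            CoarseGrainLevel(meta["level"]) if meta.get("level", "NA") != "NA" else None
        ),
        grid=df["R"].to_numpy(),
        per_m_curves={},
        average=df["V_mean"].to_numpy(),
        spread=df["V_sd"].to_numpy(),
        m_range=(lo, hi),
        kind=meta.get("kind", "unknown"),
        terminal_pair=tuple(pair.split("-")) if pair != "NA" else None,
    )
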