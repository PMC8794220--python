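"""Synthetic structure and fragment generators with known ground truth.

Three generators cover the statistical regimes the pipeline must
distinguish:

* :func:`generate_gaussian_chain` -- an ideal chain: successive CA
  displacements are independent isotropic Gaussian steps with per-component
  standard deviation b/sqrt(3), so E[R^2] over separation m is exactly
  b^2 * m.  This is the null against which the Maxwell fits, the thermal
  exponent and the zero-potential calibration are checked.
* :func:`generate_confined_globule` -- the same walk rejected outside a
  sphere of radius radius_factor * N**(1/3), giving an ensemble whose
  radius of gyration scales as N**(1/3) (compact-globule scaling).
* :func:`sample_reweighted_maxwell` -- end-to-end distances drawn from
  density proportional to M_m(R, b) * exp(-U(R)) by rejection sampling,
  so Boltzmann inversion can be tested against a known injected potential.

All generators are deterministic under a fixed seed.  The synthetic CA
traces deliberately ignore excluded volume (that is the ideal-chain null);
``hard_core`` adds a rejection radius for stress tests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, GenerationError
from .fragments import FragmentSet
from .io_structures import Atom, Chain, CoarseGrainLevel, Residue
from .maxwell import maxwell_scale


def _chain_from_coords(coords: np.ndarray, aa_types: Sequence[str] | None) -> Chain:
    N = len(coords)
    if aa_types is None:
        aa_types = ["GLY"] * N
    if len(aa_types) != N:
        raise DomainError("aa_types must have one entry per residue")
    residues = [
        Residue(
            index=i,
            aa_type=aa_types[i],
            atoms=[Atom(name="CA", element="C", xyz=np.asarray(coords[i], float))],
        )
        for i in range(N)
    ]
    return Chain(residues=residues)


def generate_gaussian_chain(
    N: int,
    b: float = 3.8,
    seed: int = 0,
    aa_types: Sequence[str] | None = None,
    hard_core: float | None = None,
    max_retries: int = 10_000,
) -> Chain:
    """CA-only ideal chain of N residues with Kuhn length ``b`` (Å)."""
    if N < 2:
        raise DomainError("N must be >= 2")
    if b <= 0:
        raise DomainError("b must be > 0")
    rng = np.random.default_rng(seed)
    sd = b / np.sqrt(3.0)
    if hard_core is None:
        steps = rng.normal(0.0, sd, size=(N - 1, 3))
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        coords = np.zeros((N, 3))
        for i in range(1, N):
            for attempt in range(max_retries + 1):
                cand = coords[i - 1] + rng.normal(0.0, sd, size=3)
                d2 = np.sum((coords[:i] - cand) ** 2, axis=1)
                if np.all(d2 >= hard_core**2):
                    coords[i] = cand
                    break
            else:
                raise GenerationError(
                    f"hard-core rejection stalled at residue {i}"
                )
    return _chain_from_coords(coords, aa_types)


def two_block_sequence(N: int, aa_first: str = "ALA", aa_second: str = "GLY") -> list[str]:
    """Block sequence: first half ``aa_first``, second half ``aa_second``.

    Gives sequence-dependent filtering non-trivial counts: fragments lying
    within one block carry a like pair, fragments straddling the boundary a
    mixed pair.
    """
    half = N // 2
    return [aa_first] * half + [aa_second] * (N - half)


def generate_confined_globule(
    N: int,
    radius_factor: float = 2.2,
    b: float = 3.8,
    seed: int = 0,
    max_retries: int = 10_000,
) -> Chain:
    """Gaussian-step walk confined to a sphere of radius radius_factor * N^(1/3)."""
    if N < 2:
        raise DomainError("N must be >= 2")
    if radius_factor <= 0:
        raise DomainError("radius_factor must be > 0")
    rng = np.random.default_rng(seed)
    radius = radius_factor * N ** (1.0 / 3.0)
    sd = b / np.sqrt(3.0)
    coords = np.zeros((N, 3))
    # pre-draw candidate steps in blocks; refill lazily on heavy rejection
    pool = rng.normal(0.0, sd, size=(4 * N, 3))
    k = 0
    for i in range(1, N):
        for attempt in range(max_retries + 1):
            if k >= len(pool):
                pool = rng.normal(0.0, sd, size=(4 * N, 3))
                k = 0
            cand = coords[i - 1] + pool[k]
            k += 1
            if cand @ cand <= radius * radius:
                coords[i] = cand
                break
        else:
            raise GenerationError(
                f"confinement rejection stalled at residue {i} "
                f"(radius {radius:.2f} Å, step sd {sd:.2f} Å)"
            )
    return _chain_from_coords(coords, None)


def gaussian_well(
    depth: float = 1.0, center: float = 10.0, width: float = 2.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Attractive Gaussian well U(R) = -depth * exp(-(R-center)^2/(2 width^2))."""

    def U(R):
        R = np.asarray(R, dtype=float)
        return -depth * np.exp(-0.5 * ((R - center) / width) ** 2)

    return U


def hard_core_potential(r_core: float) -> Callable[[np.ndarray], np.ndarray]:
    """U(R) = +inf below r_core, 0 above (pure excluded volume)."""

    def U(R):
        R = np.asarray(R, dtype=float)
        return np.where(R < r_core, np.inf, 0.0)

    return U


def sample_reweighted_maxwell(
    m: int,
    b: float,
    U: Callable[[np.ndarray], np.ndarray] | None,
    n: int,
    seed: int = 0,
    level: CoarseGrainLevel = CoarseGrainLevel.CA,
    min_acceptance: float = 1e-4,
) -> FragmentSet:
    """Draw n distances from density ∝ M_m(R, b) * exp(-U(R)) by rejection.

    The proposal is the Maxwell reference itself; acceptance probability is
    exp(-(U - U_min)) with U_min located numerically, so U must be bounded
    below.  An acceptance rate under ``min_acceptance`` raises
    :class:`GenerationError` (a tighter envelope is then needed).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scale = maxwell_scale(b, m)
    if U is None:
        draws = stats.maxwell.rvs(scale=scale, size=n, random_state=rng)
        return FragmentSet(m=m, level=level, distances=draws)
    probe = np.linspace(1e-6, 8.0 * scale, 4096)
    with np.errstate(invalid="ignore"):
        u_probe = np.asarray(U(probe), dtype=float)
    finite = np.isfinite(u_probe)
    if not finite.any():
        raise DomainError("U is nowhere finite on (0, 8*scale)")
    u_min = float(u_probe[finite].min())

    out: list[np.ndarray] = []
    accepted = 0
    proposed = 0
    batch = max(4 * n, 10_000)
    while accepted < n:
        R = stats.maxwell.rvs(scale=scale, size=batch, random_state=rng)
        with np.errstate(invalid="ignore", over="ignore"):
            u = np.asarray(U(R), dtype=float)
            p = np.exp(-(u - u_min))
        p = np.where(np.isfinite(p), p, 0.0)
        keep = rng.uniform(size=batch) < p
        out.append(R[keep])
        accepted += int(keep.sum())
        proposed += batch
        if proposed >= max(1_000_000, 10 * n) and accepted / proposed < min_acceptance:
            raise GenerationError(
                f"acceptance rate {accepted / proposed:.2e} < {min_acceptance}; "
                "use a better envelope for this U"
            )
    draws = np.concatenate(out)[:n]
    return FragmentSet(m=m, level=level, distances=draws)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: single-letter elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(chain: Chain, path: str | Path, chain_id: str = "A") -> None:
    """Write a chain as standard fixed-width PDB ATOM records."""
    lines = []
    serial = 0
    for res in chain.residues:
        for atom in res.atoms:
            serial += 1
            name = _format_atom_name(atom.name, atom.element)
            x, y, z = atom.xyz
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.aa_type:>3s} "
                f"{chain_id:1s}{res.index + 1:4d}{'':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append(
        f"TER   {serial + 1:5d}      {chain.residues[-1].aa_type:>3s} "
        f"{chain_id:1s}{chain.residues[-1].index + 1:4d}"
    )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(params: dict, path: str | Path) -> None:
    """Record generator parameters (seed included) next to the output files."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True))
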