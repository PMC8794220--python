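"""Enumeration of buried chain fragments and their end-to-end distances.

A fragment is the stretch of chain between residues i and j = i + m; m is
the *sequence separation* of its ends.  A fragment of separation m in a
chain of N residues is considered buried -- far enough from the globule
surface -- when m < N**(2/3) (strict).  All sliding windows are pooled, so
an eligible chain contributes exactly N - m fragments at separation m.

End-to-end distances are measured at the three coarse-graining levels: the
CA-CA distance, the minimum distance over heavy-atom pairs (HV), or the
minimum over all atom pairs including hydrogens (HH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainError, MissingAtomError, NoHydrogensError
from .io_structures import (
    STANDARD_AA,
    Chain,
    CoarseGrainLevel,
    Residue,
    atom_selection,
)


@dataclass(eq=False)
class FragmentSet:
    """All end-to-end distances pooled at one sequence separation m."""

    m: int
    level: CoarseGrainLevel
    distances: np.ndarray
    terminal_types: np.ndarray | None = None   # (n, 2) of 3-letter codes
    structure_ids: np.ndarray | None = None
    n_skipped: int = 0

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        self.level = CoarseGrainLevel(self.level)
        if self.distances.size and np.any(self.distances <= 0):
            raise DomainError("all end-to-end distances must be > 0")
        if self.terminal_types is not None:
            self.terminal_types = np.asarray(self.terminal_types, dtype="U3")
            if len(self.terminal_types) != len(self.distances):
                raise DomainError("terminal_types must parallel distances")

    @property
    def n(self) -> int:
        return int(self.distances.size)


def enumerate_buried_fragments(chain: Chain, m: int) -> list[tuple[int, int]]:
    """Index pairs (i, i+m) of buried fragments, or [] if m >= N**(2/3)."""
    if m < 1:
        raise DomainError("m must be >= 1")
    N = chain.N
    if not m < N ** (2.0 / 3.0):
        return []
    return [(i, i + m) for i in range(N - m)]


def end_to_end_distance(
    res_i: Residue, res_j: Residue, level: CoarseGrainLevel
) -> float:
    """Distance between two residues at the given coarse-graining level."""
    level = CoarseGrainLevel(level)
    ci = np.atleast_2d(atom_selection(res_i, level))
    cj = np.atleast_2d(atom_selection(res_j, level))
    if level is CoarseGrainLevel.CA:
        return float(np.linalg.norm(ci[0] - cj[0]))
    return float(cdist(ci, cj).min())


def collect_distances(
    chains: Sequence[Chain],
    m_range: tuple[int, int],
    level: CoarseGrainLevel,
    record_types: bool = True,
    structure_ids: Sequence | None = None,
) -> dict[int, FragmentSet]:
    """Pool buried-fragment end-to-end distances for every m in ``m_range``.

    Fragments whose terminal residues cannot provide the required atoms are
    skipped and counted in ``FragmentSet.n_skipped``.  Terminal residue
    types are recorded alongside each distance when ``record_types``.
    """
    if not chains:
        raise DomainError("collect_distances: empty ensemble")
    level = CoarseGrainLevel(level)
    m_lo, m_hi = int(m_range[0]), int(m_range[1])
    if m_lo < 1 or m_hi < m_lo:
        raise DomainError(f"bad m_range {m_range}")
    if level is CoarseGrainLevel.HH and not any(
        r.has_hydrogens for c in chains for r in c.residues
    ):
        raise NoHydrogensError(
            "HH level requested but no hydrogen atom exists in the ensemble; "
            "use HV explicitly if heavy atoms are intended"
        )
    if structure_ids is not None and len(structure_ids) != len(chains):
        raise DomainError("structure_ids must parallel chains")

    dist: dict[int, list[np.ndarray]] = {m: [] for m in range(m_lo, m_hi + 1)}
    types: dict[int, list[np.ndarray]] = {m: [] for m in dist}
    sids: dict[int, list[np.ndarray]] = {m: [] for m in dist}
    skipped = dict.fromkeys(dist, 0)

    for ci, chain in enumerate(chains):
        N = chain.N
        sid = structure_ids[ci] if structure_ids is not None else str(ci)
        aa = chain.aa_types() if record_types else None
        if level is CoarseGrainLevel.CA:
            X = chain.ca_array()
            finite = np.isfinite(X).all(axis=1)
            for m in dist:
                if not m < N ** (2.0 / 3.0):
                    continue
                d = np.linalg.norm(X[m:] - X[:-m], axis=1)
                ok = finite[m:] & finite[:-m] & (d > 0)
                skipped[m] += int((~ok).sum())
                if ok.any():
                    dist[m].append(d[ok])
                    if record_types:
                        idx = np.flatnonzero(ok)
                        types[m].append(
                            np.stack([aa[idx], aa[idx + m]], axis=1)
                        )
                    sids[m].append(np.repeat(str(sid), int(ok.sum())))
        else:
            coords = []
            for r in chain.residues:
                try:
                    coords.append(np.atleast_2d(atom_selection(r, level)))
                except MissingAtomError:
                    coords.append(None)
            for m in dist:
                if not m < N ** (2.0 / 3.0):
                    continue
                vals, tps, ss = [], [], []
                for i in range(N - m):
                    a, b = coords[i], coords[i + m]
                    if a is None or b is None:
                        skipped[m] += 1
                        continue
                    d = float(cdist(a, b).min())
                    if d <= 0:
                        skipped[m] += 1
                        continue
                    vals.append(d)
                    if record_types:
                        tps.append((aa[i], aa[i + m]))
                    ss.append(str(sid))
                if vals:
                    dist[m].append(np.asarray(vals))
                    if record_types:
                        types[m].append(np.asarray(tps, dtype="U3"))
                    sids[m].append(np.asarray(ss))

    out: dict[int, FragmentSet] = {}
    for m in dist:
        if dist[m]:
            d = np.concatenate(dist[m])
            t = np.concatenate(types[m]) if record_types else None
            s = np.concatenate(sids[m])
        else:
            d = np.empty(0)
            t = np.empty((0, 2), dtype="U3") if record_types else None
            s = np.empty(0, dtype="U32")
        out[m] = FragmentSet(
            m=m, level=level, distances=d, terminal_types=t,
            structure_ids=s, n_skipped=skipped[m],
        )
    if all(fs.n == 0 for fs in out.values()):
        warnings.warn("collect_distances: all fragment sets are empty")
    return out


def filter_by_terminal_types(fs: FragmentSet, aa1: str, aa2: str) -> FragmentSet:
    """Restrict a fragment set to fragments whose unordered terminal pair is {aa1, aa2}."""
    for code in (aa1, aa2):
        if code not in STANDARD_AA:
            raise DomainError(f"unknown amino-acid code {code!r}")
    if fs.terminal_types is None:
        raise DomainError("fragment set carries no terminal types")
    t = fs.terminal_types
    mask = ((t[:, 0] == aa1) & (t[:, 1] == aa2)) | (
        (t[:, 0] == aa2) & (t[:, 1] == aa1)
    )
    return FragmentSet(
        m=fs.m,
        level=fs.level,
        distances=fs.distances[mask],
        terminal_types=t[mask],
        structure_ids=fs.structure_ids[mask] if fs.structure_ids is not None else None,
        n_skipped=fs.n_skipped,
    )


def fragment_sets_to_tsv(sets: Mapping[int, FragmentSet], path: str | Path) -> None:
    """Serialize fragment sets to a columnar TSV (lossless reload)."""
    frames = []
    for m in sorted(sets):
        fs = sets[m]
        df = pd.DataFrame({"m": fs.m, "level": fs.level.value, "R": fs.distances})
        if fs.terminal_types is not None and len(fs.terminal_types):
            df["aa_i"] = fs.terminal_types[:, 0]
            df["aa_j"] = fs.terminal_types[:, 1]
        else:
            df["aa_i"] = ""
            df["aa_j"] = ""
        df["structure_id"] = (
            fs.structure_ids if fs.structure_ids is not None else ""
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def fragment_sets_from_tsv(path: str | Path) -> dict[int, FragmentSet]:
    df = pd.read_csv(path, sep="\t", dtype={"aa_i": str, "aa_j": str,
                                            "structure_id": str},
                     keep_default_na=False)
    out = {}
    for (m, level), grp in df.groupby(["m", "level"], sort=True):
        has_types = bool((grp["aa_i"] != "").any())
        out[int(m)] = FragmentSet(
            m=int(m),
            level=CoarseGrainLevel(level),
            distances=grp["R"].to_numpy(),
            terminal_types=(
                grp[["aa_i", "aa_j"]].to_numpy(dtype="U3") if has_types else None
            ),
            structure_ids=grp["structure_id"].to_numpy(dtype="U32"),
        )
    return out
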