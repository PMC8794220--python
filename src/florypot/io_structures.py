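"""Structure ingestion: PDB/mmCIF reading and per-residue coordinate access.

Protein chains are exposed as ordered lists of residues with their atoms, and
residue coordinates can be selected at three coarse-graining levels:

* ``CA`` -- the alpha-carbon position only;
* ``HV`` -- all heavy (non-hydrogen) atoms;
* ``HH`` -- all atoms, hydrogens included.

Parsing conventions (deliberately deterministic):

* only the first model of a multi-model file is used;
* alternate locations are resolved to the highest-occupancy conformer
  (ties resolved to the first listed);
* waters and non-peptidic ligands are dropped at parse time; non-standard
  amino acids (e.g. MSE) are retained for chain length and geometry but are
  not part of the 20-type sequence classification;
* chains are split at residue-numbering gaps, because an end-to-end distance
  measured across an unresolved stretch of chain is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    InsufficientAtomsError,
    MissingAtomError,
    StructureParseError,
)

#: The 20 standard amino-acid three-letter codes.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class CoarseGrainLevel(str, Enum):
    """The three residue-representation levels used throughout the package."""

    CA = "CA"
    HV = "HV"
    HH = "HH"


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass(eq=False)
class Residue:
    """One residue: 0-based chain position, 3-letter type, and its atoms."""

    index: int
    aa_type: str
    atoms: list[Atom]

    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA" and a.element.upper() != "CA":  # exclude calcium ions
                return a.xyz
        # CA-named atom with element left blank (common in minimal traces)
        for a in self.atoms:
            if a.name == "CA":
                return a.xyz
        return None

    @property
    def is_standard(self) -> bool:
        return self.aa_type in STANDARD_AA

    @property
    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)


@dataclass(eq=False)
class Chain:
    residues: list[Residue]

    @property
    def N(self) -> int:
        return len(self.residues)

    def ca_array(self) -> np.ndarray:
        """(N, 3) array of CA coordinates, NaN rows where the CA is absent."""
        out = np.full((self.N, 3), np.nan)
        for i, r in enumerate(self.residues):
            ca = r.ca()
            if ca is not None:
                out[i] = ca
        return out

    def aa_types(self) -> np.ndarray:
        return np.array([r.aa_type for r in self.residues], dtype="U3")


@dataclass(eq=False)
class Structure:
    id: str
    chains: list[Chain]
    source_path: str = ""


def atom_selection(residue: Residue, level: CoarseGrainLevel) -> list[np.ndarray]:
    """Coordinates representing *residue* at the given coarse-graining level.

    CA returns exactly the alpha-carbon coordinate; HV all heavy-atom
    coordinates; HH all atom coordinates including hydrogens.  A residue that
    cannot satisfy the level raises :class:`MissingAtomError` so the caller
    can decide between skipping the fragment and aborting.
    """
    level = CoarseGrainLevel(level)
    if level is CoarseGrainLevel.CA:
        ca = residue.ca()
        if ca is None:
            raise MissingAtomError(
                f"residue {residue.index} ({residue.aa_type}) has no CA atom"
            )
        return [ca]
    if level is CoarseGrainLevel.HV:
        coords = [a.xyz for a in residue.atoms if not a.is_hydrogen]
        if not coords:
            raise MissingAtomError(
                f"residue {residue.index} ({residue.aa_type}) has no heavy atoms"
            )
        return coords
    coords = [a.xyz for a in residue.atoms]
    if not coords:
        raise MissingAtomError(f"residue {residue.index} has no atoms")
    return coords


def radius_of_gyration(chain: Chain) -> float:
    """Unweighted RMS distance of the chain's CA atoms from their centroid."""
    X = chain.ca_array()
    X = X[np.isfinite(X).all(axis=1)]
    if len(X) < 2:
        raise InsufficientAtomsError(
            f"need >= 2 CA atoms for R_g, found {len(X)}"
        )
    centroid = X.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((X - centroid) ** 2, axis=1))))


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Pick one conformer per atom name: highest occupancy, first on ties."""
    chosen: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in res:
        if a.name not in chosen:
            chosen[a.name] = a
            order.append(a.name)
        elif a.occ > chosen[a.name].occ:
            chosen[a.name] = a
    atoms = []
    for name in order:
        a = chosen[name]
        xyz = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
        if not np.all(np.isfinite(xyz)):
            continue
        atoms.append(Atom(name=name, element=a.element.name, xyz=xyz))
    return atoms


def _is_peptide_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        if info.is_water():
            return False
        if info.is_amino_acid():
            return True
    # unknown code: accept only if it looks like a backbone-bearing residue
    names = {a.name for a in res}
    return "CA" in names and ("N" in names or "C" in names)


def load_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Structure file.  ``fmt`` may be ``"pdb"``, ``"mmcif"`` or ``"auto"``
        (detect from contents/extension).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    formats = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if fmt not in formats:
        raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(p), format=formats[fmt])
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with record info
        raise StructureParseError(f"cannot parse {p.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{p.name}: no models")
    model = st[0]  # first model only

    chains: list[Chain] = []
    for gchain in model:
        segment: list[tuple[int, str, list[Atom]]] = []
        prev_num: int | None = None
        for res in gchain:
            if not _is_peptide_residue(res):
                continue
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            num = res.seqid.num
            if prev_num is not None and num - prev_num not in (0, 1):
                _flush_segment(chains, segment)
                segment = []
            segment.append((num, res.name.strip().upper(), atoms))
            prev_num = num
        _flush_segment(chains, segment)

    if not chains or not any(c.N >= 2 for c in chains):
        raise EmptyStructureError(f"{p.name}: no protein chain with >= 2 residues")
    return Structure(id=p.stem, chains=chains, source_path=str(p))


def _flush_segment(chains: list[Chain], segment: list) -> None:
    if not segment:
        return
    residues = [
        Residue(index=i, aa_type=name, atoms=atoms)
        for i, (_, name, atoms) in enumerate(segment)
    ]
    chains.append(Chain(residues=residues))


def load_directory(directory: str | Path, fmt: str = "auto") -> list[Structure]:
    """Load every parsable structure file in *directory* (sorted by name)."""
    exts = {".pdb", ".ent", ".cif", ".mmcif"}
    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() in exts
    )
    structures = []
    for p in paths:
        structures.append(load_structure(p, fmt=fmt))
    return structures
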