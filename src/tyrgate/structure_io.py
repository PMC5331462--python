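"""Structures, trajectories and atom selections.

Lightweight in-memory containers for multi-frame molecular structures
(:class:`Trajectory`), plus multi-model PDB input/output backed by
MDAnalysis and a small declarative :class:`Selection` type resolving to
ordered atom-index lists.

Units are Å for coordinates and ps for times throughout the package.
Residue numbering is taken verbatim from the file (crystallographic
numbering, e.g. FimH Phe1…Thr158); no renumbering is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("tyrgate")


class TyrgateError(Exception):
    """Base class for errors raised by this package."""


class PDBParseError(TyrgateError):
    """A PDB record could not be parsed; the message names the line."""


class StructureError(TyrgateError):
    """Structurally inconsistent input (atom counts, times, masses…)."""


class PDBFormatError(TyrgateError):
    """A value does not fit the fixed-column PDB format."""


class SelectionError(TyrgateError):
    """A selection is malformed or resolves to no atoms."""


# Standard atomic masses (Da), sufficient for protein/ligand heavy atoms
# and hydrogens; selections normally exclude hydrogens anyway.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078, "FE": 55.845,
    "ZN": 65.38, "SE": 78.971, "MN": 54.938, "CU": 63.546,
}

#: Backbone atom names; ``sidechain`` selections remove these (plus OXT
#: and backbone hydrogens), ``backbone`` selections keep only these.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
_BACKBONE_EXTRA = frozenset({"OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"})


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Follows the convention used for ATOM records of standard residues:
    leading digits are stripped (``1HB`` → H) and the first letter wins
    (``CA`` in a protein residue is carbon). Two-letter elements are only
    recognised when the full stripped name matches one (CL, BR, NA…).
    """
    stripped = name.strip().lstrip("0123456789'")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if upper[0] in "HCNOSPF":
        return upper[0]
    if upper[:2] in ELEMENT_MASSES:
        return upper[:2]
    if upper[0] in ELEMENT_MASSES:
        return upper[0]
    raise StructureError(f"cannot infer element from atom name {name!r}")


def mass_of(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise StructureError(f"no mass tabulated for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology of a trajectory."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    mass: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise StructureError(f"atom {self.name} has non-positive mass {self.mass}")


@dataclass
class Frame:
    """One coordinate set (Å) over the trajectory's atom table."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    frame_index: int = 0
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"frame {self.frame_index}: coordinates must be (n, 3), "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"frame {self.frame_index}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.frame_index, self.time_ps)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared atom table.

    ``dt_ps`` records the nominal frame spacing (e.g. 2 ps for dihedral
    extraction streams, 10 ps for clustering streams); frame times must
    be strictly increasing.
    """

    atoms: list[Atom]
    frames: list[Frame]
    dt_ps: float = 2.0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for f in self.frames:
            if f.n_atoms != n:
                raise StructureError(
                    f"frame {f.frame_index} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time_ps for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frames into an ``(n_frames, n_atoms, 3)`` array."""
        return np.stack([f.coordinates for f in self.frames])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def with_frames(self, frames: Sequence[Frame], dt_ps: float | None = None) -> "Trajectory":
        return Trajectory(self.atoms, list(frames), self.dt_ps if dt_ps is None else dt_ps)

    def subset(self, indices: np.ndarray) -> "Trajectory":
        """New trajectory restricted to the given atom indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        atoms = [self.atoms[i] for i in idx]
        frames = [Frame(f.coordinates[idx], f.frame_index, f.time_ps) for f in self.frames]
        return Trajectory(atoms, frames, self.dt_ps)


# ---------------------------------------------------------------------------
# Selections


def _as_frozenset(value) -> frozenset | None:
    if value is None:
        return None
    if isinstance(value, (str, int)):
        value = (value,)
    return frozenset(value)


@dataclass(frozen=True)
class Selection:
    """Declarative predicate over atoms.

    Fields combine conjunctively. ``resids`` is an explicit residue-number
    set, ``resid_range`` an inclusive (lo, hi) pair; ``heavy_only``
    removes hydrogens; ``sidechain``/``backbone`` restrict by backbone
    membership (N, CA, C, O, OXT plus backbone hydrogens).
    """

    chain: str | None = None
    resids: frozenset | None = None
    resid_range: tuple[int, int] | None = None
    names: frozenset | None = None
    heavy_only: bool = False
    sidechain: bool = False
    backbone: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "resids", _as_frozenset(self.resids))
        object.__setattr__(self, "names", _as_frozenset(self.names))
        if self.sidechain and self.backbone:
            raise SelectionError("selection cannot be both sidechain and backbone")
        if self.resid_range is not None:
            lo, hi = self.resid_range
            if lo > hi:
                raise SelectionError(f"empty resid range {self.resid_range}")

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resids is not None and atom.resid not in self.resids:
            return False
        if self.resid_range is not None:
            lo, hi = self.resid_range
            if not lo <= atom.resid <= hi:
                return False
        if self.names is not None and atom.name not in self.names:
            return False
        if self.heavy_only and atom.element == "H":
            return False
        in_backbone = atom.name in BACKBONE_NAMES or atom.name in _BACKBONE_EXTRA
        if self.sidechain and in_backbone:
            return False
        if self.backbone and not (atom.name in BACKBONE_NAMES or atom.name == "OXT"):
            return False
        return True

    def describe(self) -> str:
        parts = []
        if self.chain is not None:
            parts.append(f"chain {self.chain}")
        if self.resids is not None:
            parts.append("resid " + " ".join(str(r) for r in sorted(self.resids)))
        if self.resid_range is not None:
            parts.append(f"resid {self.resid_range[0]}-{self.resid_range[1]}")
        if self.names is not None:
            parts.append("name " + " ".join(sorted(self.names)))
        if self.sidechain:
            parts.append("sidechain")
        if self.backbone:
            parts.append("backbone")
        if self.heavy_only:
            parts.append("noh")
        return " and ".join(parts) if parts else "all"

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse the CLI mini-language, e.g.
        ``"chain A and resid 48 and sidechain and noh"``.

        Clauses joined by ``and``: ``chain X``, ``resid N [M…]`` or
        ``resid N-M``, ``name A [B…]``, ``sidechain``, ``backbone``,
        ``noh``/``heavy``, ``all``.
        """
        kwargs: dict = {}
        for clause in [c.strip() for c in text.split(" and ")]:
            if not clause:
                continue
            tokens = clause.split()
            key = tokens[0].lower()
            if key == "all" and len(tokens) == 1:
                continue
            elif key == "chain" and len(tokens) == 2:
                kwargs["chain"] = tokens[1]
            elif key == "resid" and len(tokens) >= 2:
                if len(tokens) == 2 and "-" in tokens[1] and not tokens[1].startswith("-"):
                    lo, hi = tokens[1].split("-", 1)
                    kwargs["resid_range"] = (int(lo), int(hi))
                else:
                    kwargs["resids"] = frozenset(int(t) for t in tokens[1:])
            elif key == "name" and len(tokens) >= 2:
                kwargs["names"] = frozenset(tokens[1:])
            elif key in ("sidechain", "backbone") and len(tokens) == 1:
                kwargs[key] = True
            elif key in ("noh", "heavy") and len(tokens) == 1:
                kwargs["heavy_only"] = True
            else:
                raise SelectionError(f"cannot parse selection clause {clause!r}")
        return cls(**kwargs)


def resolve_selection(traj: Trajectory, sel: Selection) -> np.ndarray:
    """Resolve a selection to an ordered atom-index array.

    Indices follow the atom-table order, are stable across frames, and an
    empty result is an error naming the predicate.
    """
    idx = np.array([i for i, a in enumerate(traj.atoms) if sel.matches(a)], dtype=int)
    if idx.size == 0:
        raise SelectionError(f"selection {sel.describe()!r} matches no atoms")
    return idx


# ---------------------------------------------------------------------------
# PDB input/output (MDAnalysis-backed)


def _validate_pdb_text(path: Path) -> None:
    """Cheap fixed-column validation so parse errors carry line numbers."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}, line {lineno}: truncated {record} record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: malformed {record} record: {line.rstrip()!r}"
                    ) from None
                current += 1
            elif record == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif record == "ENDMDL":
                in_model = False
                counts.append(current)
                current = 0
    if not saw_model and current > 0:
        counts.append(current)
    elif in_model:  # MODEL without ENDMDL at EOF
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        raise StructureError(
            f"{path}: inconsistent atom counts across MODELs: {sorted(set(counts))}"
        )


def _altloc_keep_mask(universe) -> np.ndarray:
    """Keep the highest-occupancy alternate-location conformer only."""
    ag = universe.atoms
    altlocs = getattr(ag, "altLocs", None)
    if altlocs is None or all(a.strip() == "" for a in altlocs):
        return np.ones(len(ag), dtype=bool)
    occ = getattr(ag, "occupancies", np.ones(len(ag)))
    keep = np.ones(len(ag), dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for i, atom in enumerate(ag):
        if altlocs[i].strip() == "":
            continue
        key = (atom.segid, atom.resid, atom.name)
        groups.setdefault(key, []).append(i)
    for members in groups.values():
        if len(members) > 1:
            best = max(members, key=lambda i: (occ[i], -i))
            for i in members:
                keep[i] = i == best
    return keep


def read_multimodel_pdb(path, dt_ps: float = 2.0) -> Trajectory:
    """Read a (multi-)MODEL PDB file into a :class:`Trajectory`.

    One frame per MODEL (a file without MODEL records yields one frame).
    The element column is used when present, otherwise inferred from the
    atom name; masses come from the built-in standard table. When
    alternate-location indicators are present only the highest-occupancy
    conformer is kept. Frame times are ``frame_index * dt_ps`` — the PDB
    format carries no time metadata, so the spacing is caller-supplied.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _validate_pdb_text(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    keep = _altloc_keep_mask(u)
    ag = u.atoms[np.flatnonzero(keep)]

    file_elements = getattr(ag, "elements", None)
    atoms: list[Atom] = []
    for i, a in enumerate(ag):
        elem = ""
        if file_elements is not None:
            elem = str(file_elements[i]).strip()
        if not elem:
            elem = element_from_name(a.name)
        elem = elem.upper() if len(elem) > 1 else elem
        chain = (getattr(a, "chainID", "") or a.segid or "A").strip() or "A"
        atoms.append(
            Atom(
                serial=int(a.id),
                name=str(a.name),
                element=elem,
                resname=str(a.resname),
                resid=int(a.resid),
                chain=chain,
                mass=mass_of(elem),
            )
        )
    seen = set()
    for a in atoms:
        key = (a.chain, a.resid, a.name)
        if key in seen:
            raise StructureError(f"{path}: duplicate atom {key} within one frame")
        seen.add(key)

    frames = []
    for k, _ in enumerate(u.trajectory):
        frames.append(Frame(ag.positions.astype(float).copy(), k, k * dt_ps))
    logger.debug("read %s: %d frames, %d atoms", path, len(frames), len(atoms))
    return Trajectory(atoms, frames, dt_ps)


def _trajectory_to_universe(traj: Trajectory):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = traj.n_atoms
    reskeys: list[tuple] = []
    atom_resindex = []
    for a in traj.atoms:
        key = (a.chain, a.resid, a.resname)
        if not reskeys or reskeys[-1] != key:
            reskeys.append(key)
        atom_resindex.append(len(reskeys) - 1)
    u = mda.Universe.empty(
        n, n_residues=len(reskeys), atom_resindex=atom_resindex,
        residue_segindex=[0] * len(reskeys), trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in traj.atoms])
    u.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    u.add_TopologyAttr("chainIDs", [a.chain for a in traj.atoms])
    u.add_TopologyAttr("resnames", [k[2] for k in reskeys])
    u.add_TopologyAttr("resids", [k[1] for k in reskeys])
    u.add_TopologyAttr("occupancies", [1.0] * n)
    u.add_TopologyAttr("tempfactors", [0.0] * n)
    u.add_TopologyAttr("masses", [a.mass for a in traj.atoms])
    coords = traj.coordinate_array().astype(np.float32)
    u.load_new(coords, format=MemoryReader)
    return u


def write_multimodel_pdb(traj: Trajectory, path, single_model: bool = False) -> None:
    """Write a trajectory as a fixed-column multi-MODEL PDB file.

    Coordinates are written at 3 decimals (PDB precision). With
    ``single_model`` a one-frame trajectory is written without
    MODEL/ENDMDL records for compatibility with single-structure tools.
    """
    if traj.n_frames == 0:
        raise StructureError("cannot write an empty trajectory")
    coords = traj.coordinate_array()
    if coords.max() > 9999.999 or coords.min() < -999.999:
        raise PDBFormatError(
            "coordinates exceed the PDB fixed-column field width (%8.3f)"
        )
    if single_model and traj.n_frames != 1:
        raise PDBFormatError("single_model output requires exactly one frame")
    import MDAnalysis as mda

    u = _trajectory_to_universe(traj)
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_model:
            u.atoms.write(path)
        else:
            with mda.Writer(path, multiframe=True) as writer:
                for _ in u.trajectory:
                    writer.write(u.atoms)
    logger.debug("wrote %s: %d frames, %d atoms", path, traj.n_frames, traj.n_atoms)
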