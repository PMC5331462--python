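"""Core 3-D primitives for trajectory analysis.

Torsion angles (IUPAC sign convention, degrees in (−180, 180]), centres
of mass, Kabsch least-squares superposition, RMSD series, and rigid
rotation about a dihedral axis used to build ±n·step scan-geometry
grids for external energy engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Frame, Selection, Trajectory, TyrgateError, resolve_selection

logger = logging.getLogger("tyrgate")

_EPS = 1e-10


class GeometryError(TyrgateError):
    """Degenerate geometry (coincident/collinear points)."""


class UndefinedTorsionError(GeometryError):
    """The four points do not define a torsion angle."""


class SuperpositionError(GeometryError):
    """Superposition impossible (too few or degenerate points)."""


class TopologyError(TyrgateError):
    """A moving-atom set is inconsistent with the rotation axis."""


class MissingAtomError(TyrgateError):
    """A required backbone atom is absent from the topology."""


@dataclass(frozen=True)
class TorsionSpec:
    """Four atom indices (i, j, k, l) defining a torsion.

    For φ of residue r the atoms are C(r−1), N(r), CA(r), C(r); for ψ
    they are N(r), CA(r), C(r), N(r+1). The rotation axis of the torsion
    is the j→k bond.
    """

    i: int
    j: int
    k: int
    l: int
    label: str = "custom"
    resid: int | None = None

    def __post_init__(self) -> None:
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise TyrgateError(f"torsion atom indices must be distinct: {self}")

    @property
    def indices(self) -> tuple[int, int, int, int]:
        return (self.i, self.j, self.k, self.l)


@dataclass
class SuperpositionResult:
    """Rigid transform ``x ↦ rotation @ x + translation`` and its RMSD (Å)."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DihedralSeries:
    """Per-frame values (degrees) of one backbone torsion of one residue."""

    resid: int
    label: str  # "phi" | "psi"
    values: np.ndarray
    source_tag: str = "other"  # ligand_free | HM_bound | BF_bound | other

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (
            self.values.min() <= -180.0 - 1e-9 or self.values.max() > 180.0 + 1e-9
        ):
            raise TyrgateError("dihedral values must lie in (-180, 180]")

    def __len__(self) -> int:
        return self.values.size


def _wrap_degrees(angle):
    """Map angles into (−180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def torsion_angles(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> np.ndarray:
    """Vectorised torsion angles for stacked point quadruples.

    Inputs are (..., 3) arrays; the result is in degrees, (−180, 180],
    with the IUPAC sign convention (clockwise positive viewed from p2
    toward p3).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.any(np.linalg.norm(b - a, axis=-1) < _EPS):
            raise UndefinedTorsionError("consecutive torsion points coincide")
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(np.linalg.norm(np.cross(b0, b1n), axis=-1) < _EPS) or np.any(
        np.linalg.norm(np.cross(b2, b1n), axis=-1) < _EPS
    ):
        raise UndefinedTorsionError("collinear points do not define a torsion")
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return _wrap_degrees(np.degrees(np.arctan2(y, x)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (−180, 180]."""
    return float(torsion_angles(p1, p2, p3, p4))


# ---------------------------------------------------------------------------
# Backbone φ/ψ extraction


def _atom_index_map(traj: Trajectory) -> dict[tuple[str, int, str], int]:
    return {(a.chain, a.resid, a.name): i for i, a in enumerate(traj.atoms)}


def backbone_torsion_spec(
    traj: Trajectory, resid: int, label: str, chain: str | None = None
) -> TorsionSpec:
    """Build the φ or ψ :class:`TorsionSpec` of a residue.

    Raises :class:`MissingAtomError` when a required backbone atom
    (including the neighbouring residue's) is absent.
    """
    if chain is None:
        chains = {a.chain for a in traj.atoms if a.resid == resid}
        if not chains:
            raise MissingAtomError(f"residue {resid} not present")
        chain = sorted(chains)[0]
    amap = _atom_index_map(traj)

    def need(r: int, name: str) -> int:
        try:
            return amap[(chain, r, name)]
        except KeyError:
            raise MissingAtomError(
                f"residue {resid} {label}: missing atom {name} of residue {r} (chain {chain})"
            ) from None

    if label == "phi":
        return TorsionSpec(
            need(resid - 1, "C"), need(resid, "N"), need(resid, "CA"), need(resid, "C"),
            label="phi", resid=resid,
        )
    if label == "psi":
        return TorsionSpec(
            need(resid, "N"), need(resid, "CA"), need(resid, "C"), need(resid + 1, "N"),
            label="psi", resid=resid,
        )
    raise TyrgateError(f"unknown backbone torsion label {label!r}")


def phi_psi(
    traj: Trajectory,
    resids,
    chain: str | None = None,
    source_tag: str = "other",
) -> dict[tuple[int, str], DihedralSeries]:
    """Extract per-frame φ/ψ series for the given residues.

    Chain-terminal residues lacking the neighbour needed for φ or ψ
    yield no series for that torsion (logged as a notice). A residue
    present but missing one of its own backbone atoms raises
    :class:`MissingAtomError`.
    """
    coords = traj.coordinate_array()
    out: dict[tuple[int, str], DihedralSeries] = {}
    present = {(a.chain, a.resid) for a in traj.atoms}
    for resid in resids:
        use_chain = chain
        if use_chain is None:
            chains = sorted({c for (c, r) in present if r == resid})
            if not chains:
                raise MissingAtomError(f"residue {resid} not present in trajectory")
            use_chain = chains[0]
        for label, neighbour in (("phi", resid - 1), ("psi", resid + 1)):
            if (use_chain, neighbour) not in present:
                logger.info(
                    "residue %d: no %s (chain %s has no residue %d)",
                    resid, label, use_chain, neighbour,
                )
                continue
            spec = backbone_torsion_spec(traj, resid, label, use_chain)
            values = torsion_angles(
                coords[:, spec.i], coords[:, spec.j], coords[:, spec.k], coords[:, spec.l]
            )
            out[(resid, label)] = DihedralSeries(resid, label, values, source_tag)
    return out


# ---------------------------------------------------------------------------
# Centres of mass


def com_series(traj: Trajectory, sel: Selection) -> np.ndarray:
    """Mass-weighted centre of mass of a selection, per frame: (F, 3) Å."""
    idx = resolve_selection(traj, sel)
    m = traj.masses()[idx]
    coords = traj.coordinate_array()[:, idx]
    return np.einsum("fac,a->fc", coords, m) / m.sum()


def center_of_mass(traj: Trajectory, sel: Selection, frame_index: int = 0) -> np.ndarray:
    """Mass-weighted centre of mass of one frame's selection (Å triple)."""
    return com_series(traj, sel)[frame_index]


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _check_superposable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise SuperpositionError("superposition requires at least 3 points")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point configuration")


def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares optimal rigid (reflection-free) superposition.

    Returns the Kabsch transform mapping ``mobile`` onto ``reference``
    and the RMSD after transformation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SuperpositionError(
            f"point counts differ: {mobile.shape} vs {reference.shape}"
        )
    _check_superposable(mobile)
    _check_superposable(reference)
    w = None if weights is None else np.asarray(weights, dtype=float)
    mob_c = np.average(mobile, axis=0, weights=w)
    ref_c = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    d2 = np.sum((moved - reference) ** 2, axis=1)
    rmsd = float(np.sqrt(np.average(d2, weights=w)))
    return SuperpositionResult(R, t, rmsd)


def batched_superpose(
    mobile_stack: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch superposition of many frames onto one reference at once.

    ``mobile_stack`` is (F, m, 3); returns rotations (F, 3, 3),
    translations (F, 3) and RMSDs (F,). Reflections are corrected per
    frame via the determinant sign.
    """
    X = np.asarray(mobile_stack, dtype=float)
    Y = np.asarray(reference, dtype=float)
    _check_superposable(Y)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=0)
    C = np.einsum("fmi,mj->fij", Xc, Yc)  # covariance per frame
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    D = np.zeros((X.shape[0], 3, 3))
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    # rotation mapping mobile -> reference: R = V D U^T
    R = np.einsum("fji,fjk,flk->fil", Vt, D, U)
    t = Y.mean(axis=0) - np.einsum("fij,fj->fi", R, X.mean(axis=1))
    moved = np.einsum("fmj,fij->fmi", X, R) + t[:, None, :]
    rmsd = np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=2), axis=1))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory, ref: Frame, sel: Selection, fit_sel: Selection | None = None
) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference frame.

    Each frame is superposed on ``ref`` over ``fit_sel`` (defaults to
    ``sel``) and the RMSD is reported over ``sel`` — the standard
    backbone-fit construction.
    """
    if fit_sel is None:
        fit_sel = sel
    sel_idx = resolve_selection(traj, sel)
    fit_idx = resolve_selection(traj, fit_sel)
    coords = traj.coordinate_array()
    R, t, _ = batched_superpose(coords[:, fit_idx], ref.coordinates[fit_idx])
    moved = np.einsum("fmj,fij->fmi", coords[:, sel_idx], R) + t[:, None, :]
    diff = moved - ref.coordinates[sel_idx]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


# ---------------------------------------------------------------------------
# Rigid dihedral rotation and scan grids


def rotate_dihedral(
    frame: Frame, spec: TorsionSpec, delta: float, moving: np.ndarray
) -> Frame:
    """Rotate ``moving`` atoms rigidly about the j→k bond by ``delta`` degrees.

    The torsion defined by ``spec`` increases by exactly ``delta``
    (mod 360); internal distances within the moving set and within the
    fixed set are unchanged. ``moving`` must contain atom l (p4's side)
    and exclude atoms i and j (p1's side).
    """
    moving = np.asarray(moving, dtype=int)
    mset = set(moving.tolist())
    if spec.i in mset or spec.j in mset:
        raise TopologyError(
            "moving set intersects the fixed side of the rotation axis (atoms i/j)"
        )
    if spec.l not in mset:
        raise TopologyError("moving set must contain atom l (p4 side of the bond)")
    coords = frame.coordinates.copy()
    p2, p3 = coords[spec.j], coords[spec.k]
    axis = p3 - p2
    norm = np.linalg.norm(axis)
    if norm < _EPS:
        raise GeometryError("zero-length rotation axis")
    axis /= norm
    # IUPAC torsions are clockwise-positive viewed from j toward k, which
    # for the l-side atoms is a right-hand rotation about the j→k axis.
    rot = Rotation.from_rotvec(np.radians(delta) * axis)
    coords[moving] = rot.apply(coords[moving] - p3) + p3
    return Frame(coords, frame.frame_index, frame.time_ps)


def scan_grid(
    traj: Trajectory,
    spec: TorsionSpec,
    step: float,
    n_steps: int,
    moving: np.ndarray,
    frame_index: int = 0,
) -> Trajectory:
    """Rigid dihedral-scan geometries at offsets −n·step … +n·step.

    Returns a trajectory of ``2·n_steps + 1`` frames ordered by offset;
    the centre frame is the input frame unchanged. Energies are an
    external concern — the frames are input geometry for any engine.
    """
    if n_steps < 0:
        raise TyrgateError("n_steps must be >= 0")
    base = traj.frames[frame_index]
    frames = []
    offsets = [k * step for k in range(-n_steps, n_steps + 1)]
    for fi, off in enumerate(offsets):
        if off == 0.0:
            f = base.copy()
        else:
            f = rotate_dihedral(base, spec, off, moving)
        f.frame_index = fi
        f.time_ps = float(fi)
        frames.append(f)
    return Trajectory(traj.atoms, frames, dt_ps=1.0)
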