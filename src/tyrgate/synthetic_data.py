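"""Synthetic inputs with known ground truth.

Everything the analysis layer consumes can be generated here: idealized
toy peptides (internal-coordinate construction, no energy minimisation),
trajectories sampling prescribed dihedral wells (von Mises) or discrete
conformer mixtures, ligand-flexibility trajectory pairs with per-atom
fluctuation amplitudes, and tabulated thermodynamic curves (ITC
isotherms, LEM unfolding, 4PL dose–response).

Every generator is a pure function of (spec, seed) and returns a
ground-truth record alongside its data, so analyses can be checked
against what was actually put in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import binding_thermo as bt
from .geometry import (
    TorsionSpec,
    backbone_torsion_spec,
    torsion_angle,
)
from .structure_io import (
    Atom,
    Frame,
    Trajectory,
    TyrgateError,
    element_from_name,
    mass_of,
)

# ---------------------------------------------------------------------------
# Idealized peptide construction

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Backbone internal coordinates (Å, degrees): Engh–Huber-like ideals.
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
}

# Side-chain heavy atoms as NeRF records: (name, (a, b, c), bond, angle,
# dihedral). References are atom names within the same residue; CB uses
# the chirality-fixing dihedral C–N–CA–CB = −120° of l-amino acids.
_CB = ("CB", ("C", "N", "CA"), 1.53, 109.5, -120.0)
SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, -60.0)],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, -60.0)],
    "THR": [_CB, ("OG1", ("N", "CA", "CB"), 1.43, 109.6, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 60.0)],
    "VAL": [_CB, ("CG1", ("N", "CA", "CB"), 1.52, 110.5, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 60.0)],
    "LEU": [_CB, ("CG", ("N", "CA", "CB"), 1.53, 116.3, -60.0),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, 180.0),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, 60.0)],
    "ILE": [_CB, ("CG1", ("N", "CA", "CB"), 1.53, 110.4, -60.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 60.0),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 113.9, 180.0)],
    "PRO": [_CB, ("CG", ("N", "CA", "CB"), 1.49, 104.5, 30.0),
            ("CD", ("CA", "CB", "CG"), 1.51, 106.1, -35.0)],
    "MET": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -60.0),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.7, 180.0),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.9, 180.0)],
    "PHE": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 121.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 121.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [_CB, ("CG", ("N", "CA", "CB"), 1.51, 113.9, -60.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 121.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 121.0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)],
    "TRP": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 113.6, -60.0),
            ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, -90.0),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.40, 125.0, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.0, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.0, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.0, 0.0)],
    "ASP": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 113.0, -60.0),
            ("OD1", ("CA", "CB", "CG"), 1.25, 119.0, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0)],
    "ASN": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 112.7, -60.0),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, 180.0)],
    "GLU": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -60.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.25, 119.0, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0)],
    "GLN": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -60.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, 180.0)],
    "LYS": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -60.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.9, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0)],
    "ARG": [_CB, ("CG", ("N", "CA", "CB"), 1.52, 114.0, -60.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.5, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "HIS": [_CB, ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, 90.0),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, -90.0),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0)],
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF atom placement: position d with |cd| = bond, ∠(b,c,d) = angle
    and IUPAC torsion(a,b,c,d) = dihedral (degrees)."""
    ang, dih = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_peptide(
    sequence: str,
    phi: float | Sequence[float] = -57.0,
    psi: float | Sequence[float] = -47.0,
    omega: float = 180.0,
    start_resid: int = 1,
    chain: str = "A",
    dt_ps: float = 2.0,
) -> Trajectory:
    """Build a single-frame idealized peptide from a 1-letter sequence.

    Backbone and side-chain heavy atoms are placed from standard bond
    lengths/angles; all φ/ψ are set to the requested values (scalars or
    per-residue sequences; φ of the first and ψ of the last residue only
    orient terminal groups). Deterministic; no hydrogens, no energy
    minimisation. Atom order per residue is N, CA, [side chain], C, O —
    so the atoms moved by a φ (ψ) rotation are exactly those stored
    after CA (after C).
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 1:
        raise TyrgateError("sequence must not be empty")
    for letter in sequence:
        if letter not in AA3:
            raise TyrgateError(f"unknown residue letter {letter!r}")
    if len(sequence) == 1:
        warnings.warn("single-residue peptide: no φ/ψ torsions are defined", stacklevel=2)
    n_res = len(sequence)
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))

    # backbone trace via NeRF
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B["N-CA"], 0.0, 0.0])]
    alpha = np.radians(180.0 - _B["N-CA-C"])
    C = [CA[0] + _B["CA-C"] * np.array([np.cos(alpha), np.sin(alpha), 0.0])]
    for i in range(n_res - 1):
        N.append(_place(N[i], CA[i], C[i], _B["C-N"], _B["CA-C-N"], psis[i]))
        CA.append(_place(CA[i], C[i], N[i + 1], _B["N-CA"], _B["C-N-CA"], omega))
        C.append(_place(C[i], N[i + 1], CA[i + 1], _B["CA-C"], _B["N-CA-C"], phis[i + 1]))
    O = [
        _place(N[i], CA[i], C[i], _B["C-O"], _B["CA-C-O"], psis[i] + 180.0)
        for i in range(n_res)
    ]

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name: str, pos: np.ndarray, resname: str, resid: int) -> None:
        nonlocal serial
        elem = element_from_name(name)
        atoms.append(Atom(serial, name, elem, resname, resid, chain, mass_of(elem)))
        coords.append(pos)
        serial += 1

    for i, letter in enumerate(sequence):
        resname = AA3[letter]
        resid = start_resid + i
        local: dict[str, np.ndarray] = {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]}
        add("N", N[i], resname, resid)
        add("CA", CA[i], resname, resid)
        for name, (ra, rb, rc), bond, angle, dihedral in SIDE_CHAINS[resname]:
            pos = _place(local[ra], local[rb], local[rc], bond, angle, dihedral)
            local[name] = pos
            add(name, pos, resname, resid)
        add("C", C[i], resname, resid)
        add("O", O[i], resname, resid)
        if i == n_res - 1:
            add("OXT", _place(N[i], CA[i], C[i], 1.25, 117.0, psis[i]), resname, resid)

    frame = Frame(np.array(coords), 0, 0.0)
    return Trajectory(atoms, [frame], dt_ps)


# ---------------------------------------------------------------------------
# Ligand templates

#: Pyranose-ring atom names shared by both ligand templates; used as the
#: default alignment selection for ligand flexibility profiles.
RING_ATOM_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5")


def _hexagon(radius: float = 1.43) -> np.ndarray:
    ang = np.radians(60.0 * np.arange(6) - 90.0)
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def build_ligand(kind: str = "heptyl", dt_ps: float = 2.0) -> Trajectory:
    """Build a single-frame idealized mannoside-like ligand.

    ``heptyl`` is a pyranose-like ring carrying hydroxyls plus a
    seven-carbon aglycon tail (C1A…C7A) on the anomeric oxygen;
    ``biphenyl`` replaces the tail with two fused-geometry phenyl rings
    (CB1…CB6, CC1…CC6). Atoms are ordered anomeric-carbon outward, as
    flexibility profiles are plotted. Geometry is schematic (planar
    ring), adequate for the purely statistical analyses tested here.
    """
    ring = _hexagon()
    names = list(RING_ATOM_NAMES)
    coords = [ring[i] for i in range(6)]
    # ring substituents: anomeric O1 on C1, hydroxyls on C2–C4, C6/O6 on C5
    def outward(i: int, length: float, z: float) -> np.ndarray:
        direction = ring[i] / np.linalg.norm(ring[i])
        return ring[i] + length * direction + np.array([0.0, 0.0, z])

    names += ["O2", "O3", "O4", "C6", "O6"]
    coords += [outward(1, 1.42, 0.5), outward(2, 1.42, -0.5), outward(3, 1.42, 0.5),
               outward(4, 1.52, -0.5), outward(4, 2.9, 0.3)]
    names.append("O1")
    o1 = outward(0, 1.41, -0.4)
    coords.append(o1)
    tail_dir = ring[0] / np.linalg.norm(ring[0])
    if kind == "heptyl":
        for k in range(1, 8):
            names.append(f"C{k}A")
            coords.append(o1 + tail_dir * 1.3 * k + np.array([0.0, 0.0, 0.45 * (k % 2)]))
    elif kind == "biphenyl":
        for r, prefix in ((1, "CB"), (2, "CC")):
            center = o1 + tail_dir * (1.4 + 2.5 * (2 * r - 1) / 2.0)
            hexagon = _hexagon(1.39)
            # rings stood perpendicular to the pyranose plane
            local = np.column_stack([hexagon[:, 0], hexagon[:, 2], hexagon[:, 1]])
            for v in range(6):
                names.append(f"{prefix}{v + 1}")
                coords.append(center + local[v, 0] * tail_dir
                              + np.array([0.0, 0.0, 1.0]) * local[v, 2]
                              + np.array([0.0, 1.0, 0.0]) * local[v, 1] * 0.2)
    else:
        raise TyrgateError(f"unknown ligand template {kind!r}")
    atoms = []
    for serial, name in enumerate(names, start=1):
        elem = element_from_name(name)
        atoms.append(Atom(serial, name, elem, "LIG", 1, "X", mass_of(elem)))
    return Trajectory(atoms, [Frame(np.array(coords), 0, 0.0)], dt_ps)


# ---------------------------------------------------------------------------
# Trajectory generation


@dataclass
class TrajectorySpec:
    """Recipe for a synthetic trajectory over a template topology.

    Exactly one of ``torsion_laws`` (per-torsion von Mises wells,
    ``{(resid, "phi"|"psi"): (mu_deg, kappa)}``) or ``conformers`` (a
    discrete mixture: list of torsion dictionaries plus weights) drives
    the backbone; ``sigma`` (Å, scalar or per-atom) adds isotropic
    Gaussian jitter per coordinate on top.
    """

    template: Trajectory
    n_frames: int
    torsion_laws: dict | None = None
    conformers: list[dict] | None = None
    weights: list[float] | None = None
    sigma: float | np.ndarray = 0.0
    dt_ps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise TyrgateError("n_frames must be >= 1")
        if (self.torsion_laws is None) == (self.conformers is None):
            raise TyrgateError("specify exactly one of torsion_laws or conformers")
        if self.conformers is not None:
            if self.weights is None or len(self.weights) != len(self.conformers):
                raise TyrgateError("conformers require matching weights")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise TyrgateError("conformer weights must sum to 1")
        if self.torsion_laws is not None:
            for key, (_, kappa) in self.torsion_laws.items():
                if not kappa > 0:
                    raise TyrgateError(f"kappa must be positive for torsion {key}")
        if np.any(np.asarray(self.sigma) < 0):
            raise TyrgateError("sigma must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually sampled, for truth-aware comparisons."""

    seed: int
    sigma: np.ndarray
    conformer_labels: np.ndarray | None = None
    sampled_angles: dict | None = None
    extras: dict = field(default_factory=dict)


def _resolve_torsion(traj: Trajectory, key) -> tuple[TorsionSpec, np.ndarray]:
    """Resolve a torsion key to its spec and the downstream moving set.

    Relies on the builder's chain-ordered atom layout: every atom stored
    after the third torsion atom (k) moves when the torsion turns.
    """
    if isinstance(key, TorsionSpec):
        spec = key
    else:
        resid, label = key
        spec = backbone_torsion_spec(traj, resid, label)
    moving = np.arange(spec.k + 1, traj.n_atoms)
    return spec, moving


def _apply_torsions(traj: Trajectory, frame: Frame, targets: dict) -> Frame:
    """Return a frame with each keyed torsion set to its target angle."""
    from .geometry import rotate_dihedral

    out = frame
    for key in sorted(targets, key=lambda k: _resolve_torsion(traj, k)[0].k):
        spec, moving = _resolve_torsion(traj, key)
        coords = out.coordinates
        current = torsion_angle(
            coords[spec.i], coords[spec.j], coords[spec.k], coords[spec.l]
        )
        out = rotate_dihedral(out, spec, targets[key] - current, moving)
    return out


def _exact_proportion_labels(weights: Sequence[float], n: int, rng) -> np.ndarray:
    """Label array with populations matching the weights exactly
    (largest-remainder apportionment), in seed-shuffled order."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    for _ in range(n - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    labels = np.repeat(np.arange(len(counts)), counts)
    return labels[rng.permutation(n)]


def generate_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, GroundTruth]:
    """Sample a trajectory from a :class:`TrajectorySpec`.

    Frames are built by setting torsions via rigid dihedral rotation
    (von Mises wells or discrete conformers) and adding per-atom
    Gaussian jitter; bit-for-bit reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    base = template.frames[0]
    n, n_atoms = spec.n_frames, template.n_atoms
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (n_atoms,))

    truth = GroundTruth(seed=spec.seed, sigma=sigma.copy())
    if spec.conformers is not None:
        conf_coords = [
            _apply_torsions(template, base, conf).coordinates for conf in spec.conformers
        ]
        labels = _exact_proportion_labels(spec.weights, n, rng)
        stack = np.stack([conf_coords[lab] for lab in labels])
        truth.conformer_labels = labels
    else:
        keys = sorted(spec.torsion_laws, key=lambda k: _resolve_torsion(template, k)[0].k)
        sampled = {
            key: np.degrees(
                rng.vonmises(np.radians(spec.torsion_laws[key][0]),
                             spec.torsion_laws[key][1], size=n)
            )
            for key in keys
        }
        truth.sampled_angles = sampled
        stack = np.empty((n, n_atoms, 3))
        for f in range(n):
            frame = _apply_torsions(template, base, {k: sampled[k][f] for k in keys})
            stack[f] = frame.coordinates
    if np.any(sigma > 0):
        stack = stack + rng.normal(size=stack.shape) * sigma[None, :, None]
    frames = [Frame(stack[f], f, f * spec.dt_ps) for f in range(n)]
    return template.with_frames(frames, dt_ps=spec.dt_ps), truth


@dataclass
class BoundUnboundPair:
    """A ligand-free / ligand-bound trajectory pair with shared truth."""

    free: Trajectory
    bound: Trajectory
    truth_free: GroundTruth
    truth_bound: GroundTruth
    target: tuple
    shift: float


def generate_bound_unbound_pair(
    spec: TrajectorySpec, shift: float, target
) -> BoundUnboundPair:
    """Two trajectories identical in law except the target torsion's
    well mean is displaced by ``shift`` degrees in the second."""
    if spec.torsion_laws is None or target not in spec.torsion_laws:
        raise TyrgateError(f"unknown target torsion {target!r}")
    seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(spec.seed).spawn(2)
    ]
    mu, kappa = spec.torsion_laws[target]
    shifted = dict(spec.torsion_laws)
    shifted[target] = (mu + shift, kappa)
    free, truth_free = generate_trajectory(replace(spec, seed=seeds[0]))
    bound, truth_bound = generate_trajectory(
        replace(spec, torsion_laws=shifted, seed=seeds[1])
    )
    return BoundUnboundPair(free, bound, truth_free, truth_bound, target, shift)


@dataclass
class LigandTrajectories:
    """Free-in-water and protein-bound ligand trajectories plus truth."""

    water: Trajectory
    bound: Trajectory
    truth: GroundTruth


def default_ligand_sigmas(template: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Default fluctuation amplitudes: a quiet ring (0.05 Å) with a tail
    ramping 0.1→0.5 Å in water, halved on the tail when bound —
    emulating an aglycon clamped by the tyrosine gate."""
    names = [a.name for a in template.atoms]
    tail = [n for n in names if n not in RING_ATOM_NAMES]
    sigma_free = np.empty(len(names))
    for i, n in enumerate(names):
        if n in RING_ATOM_NAMES:
            sigma_free[i] = 0.05
        else:
            sigma_free[i] = 0.1 + 0.4 * tail.index(n) / max(len(tail) - 1, 1)
    sigma_bound = np.where(
        np.isin(names, RING_ATOM_NAMES), sigma_free, sigma_free / 2.0
    )
    return sigma_free, sigma_bound


def generate_ligand_trajectories(
    template: str | Trajectory = "heptyl",
    sigma_free: np.ndarray | None = None,
    sigma_bound: np.ndarray | None = None,
    n_frames: int = 10_000,
    seed: int = 0,
    tumble: bool = True,
) -> LigandTrajectories:
    """Paired ligand trajectories with known per-atom fluctuation truth.

    Per-frame isotropic Gaussian jitter of amplitude ``sigma_free``
    (water) / ``sigma_bound`` (bound) per atom; the water trajectory
    additionally tumbles rigidly (random rotation + translation per
    frame), which ring-alignment must remove. The truth record carries
    the analytic expectations rmsf = σ·√3 and their difference.
    """
    from scipy.spatial.transform import Rotation

    if isinstance(template, str):
        template = build_ligand(template)
    n_atoms = template.n_atoms
    if sigma_free is None or sigma_bound is None:
        default_free, default_bound = default_ligand_sigmas(template)
        sigma_free = default_free if sigma_free is None else np.asarray(sigma_free, float)
        sigma_bound = default_bound if sigma_bound is None else np.asarray(sigma_bound, float)
    sigma_free = np.broadcast_to(np.asarray(sigma_free, float), (n_atoms,))
    sigma_bound = np.broadcast_to(np.asarray(sigma_bound, float), (n_atoms,))

    rng = np.random.default_rng(seed)
    base = template.frames[0].coordinates

    def make(sig: np.ndarray, do_tumble: bool) -> Trajectory:
        stack = base[None] + rng.normal(size=(n_frames, n_atoms, 3)) * sig[None, :, None]
        if do_tumble:
            rots = Rotation.random(n_frames, rng=rng)
            shifts = rng.normal(scale=5.0, size=(n_frames, 3))
            stack = np.einsum("fij,faj->fai", rots.as_matrix(), stack) + shifts[:, None, :]
        frames = [Frame(stack[f], f, f * template.dt_ps) for f in range(n_frames)]
        return template.with_frames(frames)

    water = make(sigma_free, tumble)
    bound = make(sigma_bound, False)
    expected_free = sigma_free * np.sqrt(3.0)
    expected_bound = sigma_bound * np.sqrt(3.0)
    truth = GroundTruth(
        seed=seed,
        sigma=sigma_free.copy(),
        extras={
            "sigma_bound": sigma_bound.copy(),
            "expected_rmsf_free": expected_free,
            "expected_rmsf_bound": expected_bound,
            "expected_delta_rmsf": expected_bound - expected_free,
        },
    )
    return LigandTrajectories(water, bound, truth)


# ---------------------------------------------------------------------------
# Thermodynamic curve generation


@dataclass
class CurveSpec:
    """Recipe for a synthetic thermodynamic curve.

    ``model`` is one of ``itc_isotherm``, ``unfolding_lem`` or
    ``logistic_4pl``; ``params`` are the true model parameters, ``noise``
    the Gaussian noise amplitude as a fraction of the curve span.
    """

    model: str
    params: dict
    grid: np.ndarray | None = None
    noise: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("itc_isotherm", "unfolding_lem", "logistic_4pl"):
            raise TyrgateError(f"unknown curve model {self.model!r}")
        if self.noise < 0:
            raise TyrgateError("noise must be >= 0")
        if self.grid is not None:
            grid = np.asarray(self.grid, dtype=float)
            if np.any(np.diff(grid) <= 0):
                raise TyrgateError("grid must be strictly increasing")
            self.grid = grid


def generate_curve(spec: CurveSpec) -> tuple[pd.DataFrame, dict]:
    """Evaluate the requested model on its grid and add Gaussian noise.

    Returns the data table and the truth record (the exact parameters
    used, including defaults filled in).
    """
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.params)
    if spec.model == "itc_isotherm":
        params.setdefault("Mt0", 10e-6)
        params.setdefault("V0", 1.4523e-3)
        params.setdefault("offset", 0.0)
        # a titration of 52 equal injections to ratio 2 (experiments used
        # 38-66 injections with complete saturation)
        grid = spec.grid if spec.grid is not None else np.linspace(2.0 / 52, 2.0, 52)
        clean = bt.itc_injection_heats(
            grid, params["n"], params["Kd"], params["dH"],
            params["Mt0"], params["V0"], params["offset"],
        )
        noisy = clean + rng.normal(size=clean.shape) * spec.noise * np.ptp(clean)
        df = pd.DataFrame({"molar_ratio": grid, "heat_kJ_per_mol": noisy})
    elif spec.model == "unfolding_lem":
        params.setdefault("a_n", 1.0)
        params.setdefault("b_n", -0.015)
        params.setdefault("a_u", 0.05)
        params.setdefault("b_u", 0.005)
        params.setdefault("T", bt.T_DEFAULT)
        grid = spec.grid if spec.grid is not None else np.linspace(0.0, 6.0, 25)
        clean = bt.lem_signal(
            grid, params["dG_fold"], params["m"], params["a_n"], params["b_n"],
            params["a_u"], params["b_u"], params["T"],
        )
        noisy = clean + rng.normal(size=clean.shape) * spec.noise * np.ptp(clean)
        df = pd.DataFrame({"denaturant_M": grid, "signal": noisy})
    else:  # logistic_4pl
        params.setdefault("top", 1.0)
        params.setdefault("bottom", 0.0)
        params.setdefault("hill", 1.0)
        grid = spec.grid if spec.grid is not None else np.logspace(-8.5, -3.5, 11)
        clean = bt.logistic_4pl(
            grid, params["top"], params["bottom"], params["ic50"], params["hill"]
        )
        reps = []
        for _ in range(max(spec.replicates, 1)):
            reps.append(clean + rng.normal(size=clean.shape) * spec.noise * np.ptp(clean))
        df = pd.DataFrame({
            "concentration_M": np.tile(grid, len(reps)),
            "response": np.concatenate(reps),
        })
    return df, params
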