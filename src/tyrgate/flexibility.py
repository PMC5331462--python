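"""Per-atom fluctuation (r.m.s.f.) and Δr.m.s.f. profiles.

The r.m.s.f. of atom i over N frames is sqrt((1/N) Σ_n |p_n,i − ⟨p_i⟩|²),
the movement of the atom around its position in the trajectory-average
structure, computed after a stated rigid superposition. Δr.m.s.f.
compares a ligand's flexibility bound to the protein with its
flexibility free in water; because the mannose moiety stays put in the
binding site, ligand profiles are computed after aligning the pyranose
ring, so the aglycon's residual mobility is what remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import batched_superpose
from .structure_io import Selection, Trajectory, TyrgateError, resolve_selection


@dataclass
class FluctuationProfile:
    """Per-atom r.m.s.f. (Å) over labelled atoms after one alignment."""

    labels: list[str]
    rmsf: np.ndarray
    n_frames: int
    alignment: str = "none"

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.labels) != self.rmsf.size:
            raise TyrgateError("labels and rmsf lengths differ")
        if np.any(self.rmsf < 0):
            raise TyrgateError("rmsf must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"atom": self.labels, "rmsf_A": self.rmsf})


@dataclass
class DeltaProfile:
    """Bound-minus-free r.m.s.f. difference; negative = binding restricts."""

    labels: list[str]
    delta_rmsf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"atom": self.labels, "delta_rmsf_A": self.delta_rmsf})


def rmsf(
    traj: Trajectory, sel: Selection, align_sel: Selection | None = None
) -> FluctuationProfile:
    """r.m.s.f. of the selected atoms around the average structure.

    Frames are first superposed onto the first frame over ``align_sel``
    (``None`` means the frames are already aligned), the average
    structure is the per-atom mean of the aligned coordinates, and the
    fluctuation is the root-mean-square deviation from it. A single
    alignment pass to frame 1 is used; iterating to the evolving mean
    changes nothing at the fluctuation scales of interest.
    """
    if traj.n_frames < 2:
        raise TyrgateError("r.m.s.f. needs at least 2 frames")
    sel_idx = resolve_selection(traj, sel)
    coords = traj.coordinate_array()
    if align_sel is not None:
        fit_idx = resolve_selection(traj, align_sel)
        R, t, _ = batched_superpose(coords[:, fit_idx], coords[0, fit_idx])
        coords = np.einsum("faj,fij->fai", coords, R) + t[:, None, :]
        alignment = align_sel.describe()
    else:
        alignment = "none (pre-aligned frames)"
    x = coords[:, sel_idx]
    mean = x.mean(axis=0)
    values = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    labels = [traj.atoms[i].name for i in sel_idx]
    return FluctuationProfile(labels, values, traj.n_frames, alignment)


def delta_rmsf(bound: FluctuationProfile, free: FluctuationProfile) -> DeltaProfile:
    """Elementwise bound − free fluctuation difference.

    The two profiles must cover exactly the same atoms in the same
    order; mismatches are reported atom by atom.
    """
    if bound.labels != free.labels:
        offending = sorted(set(bound.labels) ^ set(free.labels)) or ["(ordering differs)"]
        raise TyrgateError(f"atom labels mismatch between profiles: {offending}")
    return DeltaProfile(list(bound.labels), bound.rmsf - free.rmsf)


def ligand_rmsf_mannose_aligned(
    traj: Trajectory, ligand_sel: Selection, ring_sel: Selection
) -> FluctuationProfile:
    """Ligand heavy-atom r.m.s.f. after superposing the pyranose ring.

    ``ring_sel`` must resolve to ≥3 atoms forming a subset of
    ``ligand_sel``; the profile is reported over the ligand heavy atoms
    in topology order (anomeric carbon outward).
    """
    ligand_idx = resolve_selection(traj, ligand_sel)
    ring_idx = resolve_selection(traj, ring_sel)
    if ring_idx.size < 3:
        raise TyrgateError("ring selection must contain at least 3 atoms")
    if not set(ring_idx.tolist()) <= set(ligand_idx.tolist()):
        raise TyrgateError("ring selection must be a subset of the ligand selection")
    heavy = Selection(
        chain=ligand_sel.chain, resids=ligand_sel.resids,
        resid_range=ligand_sel.resid_range, names=ligand_sel.names,
        heavy_only=True, sidechain=ligand_sel.sidechain, backbone=ligand_sel.backbone,
    )
    return rmsf(traj, heavy, align_sel=ring_sel)


def average_profiles(profiles: list[FluctuationProfile]) -> FluctuationProfile:
    """Mean r.m.s.f. across replicate trajectories of the same atoms.

    Replicates are averaged before any Δr.m.s.f. subtraction; keep the
    per-replicate profiles when replicate-level spread matters.
    """
    if not profiles:
        raise TyrgateError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.labels != first.labels:
            raise TyrgateError("replicate profiles cover different atoms")
    stacked = np.stack([p.rmsf for p in profiles])
    return FluctuationProfile(
        list(first.labels), stacked.mean(axis=0),
        sum(p.n_frames for p in profiles), first.alignment,
    )
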