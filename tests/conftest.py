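"""Shared fixtures: small synthetic systems with known ground truth."""

import numpy as np
import pytest
from hypothesis import settings

from tyrgate import Selection, Trajectory, Frame, Atom
from tyrgate import synthetic_data as sd

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix():
    """Idealized α-helical pentapeptide (φ = −57°, ψ = −47°)."""
    return sd.build_toy_peptide("NAYNS")


@pytest.fixture(scope="session")
def ile_peptide():
    """Tripeptide carrying Ile52, numbered as in the FimH lectin domain."""
    return sd.build_toy_peptide("AIA", start_resid=51)


@pytest.fixture(scope="session")
def gate_mixture():
    """1000-frame mixture of three rigid gate conformers at 50/30/20%."""
    template = sd.build_toy_peptide("AYA", start_resid=47)
    conformers = [
        {(48, "phi"): -140.0, (48, "psi"): 140.0},
        {(48, "phi"): -60.0, (48, "psi"): -45.0},
        {(48, "phi"): 60.0, (48, "psi"): 45.0},
    ]
    spec = sd.TrajectorySpec(
        template=template, n_frames=1000, conformers=conformers,
        weights=[0.5, 0.3, 0.2], sigma=0.02, seed=11,
    )
    traj, truth = sd.generate_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def ligand_pair():
    """Default heptyl-mannoside water/bound trajectory pair, 10⁴ frames."""
    return sd.generate_ligand_trajectories(n_frames=10_000, seed=7)


def random_point_trajectory(rng, n_frames, n_atoms=4):
    """Unit-topology trajectory of random coordinates for clustering tests."""
    atoms = [
        Atom(i + 1, f"C{i + 1}", "C", "UNK", 1, "A", 12.011) for i in range(n_atoms)
    ]
    frames = [
        Frame(rng.normal(scale=2.0, size=(n_atoms, 3)), f, float(f))
        for f in range(n_frames)
    ]
    return Trajectory(atoms, frames, dt_ps=1.0)


def brute_force_daura(rmsd, cutoff):
    """Independent re-implementation of the greedy neighbour-count rule.

    Plain python loops over an explicit RMSD matrix; returns a list of
    (sorted member tuple, representative) in formation order.
    """
    n = rmsd.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if rmsd[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = tuple(sorted(j for j in remaining if rmsd[best, j] <= cutoff))
        clusters.append((members, best))
        remaining -= set(members)
    return clusters


ALL = Selection()
HEAVY = Selection(heavy_only=True)
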