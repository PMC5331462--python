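"""Torsion, superposition, RMSD and dihedral-rotation primitives."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from tyrgate import (
    Selection,
    TorsionSpec,
    center_of_mass,
    phi_psi,
    rmsd_series,
    rotate_dihedral,
    scan_grid,
    superpose,
    torsion_angle,
)
from tyrgate import synthetic_data as sd
from tyrgate.geometry import (
    MissingAtomError,
    SuperpositionError,
    TopologyError,
    UndefinedTorsionError,
    torsion_angles,
)
from tyrgate.structure_io import Frame, resolve_selection


def _rotate_about_axis(point, origin, axis, angle_deg):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(point - origin) + origin


class TestTorsionAngle:
    def test_planar_trans_and_cis(self):
        trans = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        cis = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert torsion_angle(*map(np.array, trans)) == pytest.approx(180.0)
        assert torsion_angle(*map(np.array, cis)) == pytest.approx(0.0)

    @pytest.mark.parametrize("target", [60.0, -60.0, 135.0, -179.0, 179.0])
    def test_constructed_rotation_from_cis(self, target):
        # constructive oracle: rotate p4 away from the cis position about
        # the p2->p3 axis; torsion sign follows the rotation sense
        p1, p2, p3 = np.array([0.0, 1, 0]), np.zeros(3), np.array([1.0, 0, 0])
        p4_cis = np.array([1.0, 1.0, 0.0])
        p4 = _rotate_about_axis(p4_cis, p3, p3 - p2, target)
        assert torsion_angle(p1, p2, p3, p4) == pytest.approx(target, abs=1e-9)

    def test_matches_mdanalysis_convention(self):
        # independent route: same quadruples through MDAnalysis
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(0)
        quads = rng.normal(scale=3.0, size=(50, 4, 3))
        mine = torsion_angles(quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3])
        ref = np.degrees(
            calc_dihedrals(quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3])
        )
        np.testing.assert_allclose(mine, ref, atol=2e-4)  # reference path is float32

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=2.0, size=(4, 3))
        rot = Rotation.random(rng=rng)
        shift = rng.normal(scale=10.0, size=3)
        before = torsion_angle(*pts)
        after = torsion_angle(*(rot.apply(pts) + shift))
        assert np.isclose(
            (after - before + 180.0) % 360.0 - 180.0, 0.0, atol=1e-8
        )

    def test_degenerate_points_raise(self):
        p = np.zeros(3)
        with pytest.raises(UndefinedTorsionError):
            torsion_angle(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1, 0]))
        collinear = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(UndefinedTorsionError):
            torsion_angle(*collinear)


class TestPhiPsi:
    def test_helix_reextraction(self, helix):
        series = phi_psi(helix, [2, 3, 4])
        for (resid, label), ds in series.items():
            expected = -57.0 if label == "phi" else -47.0
            assert ds.values[0] == pytest.approx(expected, abs=1e-6)

    def test_chain_terminal_residues_have_no_outer_torsion(self, helix):
        series = phi_psi(helix, [1, 5])
        assert (1, "phi") not in series and (1, "psi") in series
        assert (5, "psi") not in series and (5, "phi") in series

    def test_series_length_matches_2ps_50ns_stream(self, helix):
        # 50 ns at one frame per 2 ps, inclusive of frame 0
        spec = sd.TrajectorySpec(
            template=helix, n_frames=25_001,
            torsion_laws={(3, "phi"): (-60.0, 10.0)}, sigma=0.0, seed=1, dt_ps=2.0,
        )
        traj, _ = sd.generate_trajectory(spec)
        series = phi_psi(traj, [3])
        assert len(series[(3, "phi")]) == 25_001
        assert traj.frames[-1].time_ps == pytest.approx(50_000.0)

    def test_missing_backbone_atom_is_reported(self, helix):
        broken = helix.subset(
            np.array([i for i, a in enumerate(helix.atoms)
                      if not (a.resid == 3 and a.name == "CA")])
        )
        with pytest.raises(MissingAtomError, match="CA"):
            phi_psi(broken, [3])


class TestCenterOfMass:
    def test_single_atom(self, ile_peptide):
        sel = Selection(resids={52}, names={"CB"})
        idx = resolve_selection(ile_peptide, sel)[0]
        np.testing.assert_allclose(
            center_of_mass(ile_peptide, sel), ile_peptide.frames[0].coordinates[idx]
        )

    def test_equal_mass_midpoint(self, ile_peptide):
        sel = Selection(resids={52}, names={"CG1", "CG2"})
        idx = resolve_selection(ile_peptide, sel)
        expected = ile_peptide.frames[0].coordinates[idx].mean(axis=0)
        np.testing.assert_allclose(center_of_mass(ile_peptide, sel), expected, atol=1e-12)

    def test_matches_brute_force_weighted_sum(self, ile_peptide):
        sel = Selection(resids={52}, sidechain=True, heavy_only=True)
        idx = resolve_selection(ile_peptide, sel)
        masses = ile_peptide.masses()[idx]
        coords = ile_peptide.frames[0].coordinates[idx]
        brute = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        np.testing.assert_allclose(center_of_mass(ile_peptide, sel), brute, atol=1e-12)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        pts = np.random.default_rng(2).normal(size=(8, 3))
        res = superpose(pts, pts + 5.0)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.translation, [5.0, 5.0, 5.0], atol=1e-9)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        axis = rng.normal(size=3)
        rot = Rotation.from_rotvec(np.radians(37.0) * axis / np.linalg.norm(axis))
        res = superpose(pts, rot.apply(pts))
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_rmsd_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        assert superpose(a, b).rmsd == pytest.approx(superpose(b, a).rmsd, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(SuperpositionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(SuperpositionError):
            superpose(line, line)


class TestRmsdSeries:
    def test_copies_of_reference_give_zero(self, helix):
        frames = [helix.frames[0].copy() for _ in range(4)]
        for i, f in enumerate(frames):
            f.frame_index, f.time_ps = i, float(i)
        traj = helix.with_frames(frames)
        out = rmsd_series(traj, helix.frames[0], Selection())
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_single_frame_vs_itself(self, helix):
        out = rmsd_series(helix, helix.frames[0], Selection())
        assert out.shape == (1,)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_expectation(self):
        # Monte-Carlo oracle: rmsd after fitting loses ~k=6 of 3N dof
        rng = np.random.default_rng(42)
        n_atoms, n_frames, sigma = 50, 5_000, 0.3
        ref = rng.normal(scale=4.0, size=(n_atoms, 3))
        atoms = sd.build_toy_peptide("NAYNSNAYNSNAY").atoms[:n_atoms]
        frames = [
            Frame(ref + rng.normal(scale=sigma, size=(n_atoms, 3)), f, float(f))
            for f in range(n_frames)
        ]
        from tyrgate import Trajectory

        traj = Trajectory(atoms, frames, dt_ps=1.0)
        out = rmsd_series(traj, Frame(ref), Selection())
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3.0 * n_atoms))
        assert np.mean(out) == pytest.approx(expected, rel=0.10)


@pytest.fixture(scope="module")
def torsion_setup(helix):
    from tyrgate.synthetic_data import _resolve_torsion

    spec, moving = _resolve_torsion(helix, (3, "psi"))
    return helix.frames[0], spec, moving


class TestRotateDihedral:
    def test_zero_delta_is_identity(self, torsion_setup):
        frame, spec, moving = torsion_setup
        out = rotate_dihedral(frame, spec, 0.0, moving)
        np.testing.assert_allclose(out.coordinates, frame.coordinates, atol=1e-12)

    def test_ten_steps_of_two_degrees(self, torsion_setup):
        frame, spec, moving = torsion_setup
        before = torsion_angle(*frame.coordinates[list(spec.indices)])
        out = frame
        for _ in range(10):
            out = rotate_dihedral(out, spec, 2.0, moving)
        after = torsion_angle(*out.coordinates[list(spec.indices)])
        assert (after - before + 180.0) % 360.0 - 180.0 == pytest.approx(20.0, abs=1e-9)

    def test_rigid_body_invariance_of_moving_set(self, torsion_setup):
        frame, spec, moving = torsion_setup
        out = rotate_dihedral(frame, spec, 73.0, moving)
        before = frame.coordinates[moving]
        after = out.coordinates[moving]
        d_before = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d_after = np.linalg.norm(after[:, None] - after[None], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-12)
        fixed = np.setdiff1d(np.arange(frame.n_atoms), moving)
        np.testing.assert_allclose(
            out.coordinates[fixed], frame.coordinates[fixed], atol=1e-12
        )

    @given(st.floats(-179.0, 179.0))
    def test_rotation_is_reversible(self, torsion_setup, delta):
        frame, spec, moving = torsion_setup
        out = rotate_dihedral(rotate_dihedral(frame, spec, delta, moving),
                              spec, -delta, moving)
        np.testing.assert_allclose(out.coordinates, frame.coordinates, atol=1e-9)

    def test_moving_set_must_exclude_axis_side(self, torsion_setup):
        frame, spec, moving = torsion_setup
        with pytest.raises(TopologyError):
            rotate_dihedral(frame, spec, 10.0, np.append(moving, spec.i))
        with pytest.raises(TopologyError):
            rotate_dihedral(frame, spec, 10.0, np.setdiff1d(moving, [spec.l]))


class TestScanGrid:
    def test_grid_shape_and_center(self, helix):
        from tyrgate.synthetic_data import _resolve_torsion

        spec, moving = _resolve_torsion(helix, (3, "psi"))
        grid = scan_grid(helix, spec, step=2.0, n_steps=10, moving=moving)
        assert grid.n_frames == 21
        np.testing.assert_allclose(
            grid.frames[10].coordinates, helix.frames[0].coordinates, atol=1e-12
        )

    def test_zero_steps_returns_input(self, helix):
        from tyrgate.synthetic_data import _resolve_torsion

        spec, moving = _resolve_torsion(helix, (3, "phi"))
        grid = scan_grid(helix, spec, 2.0, 0, moving)
        assert grid.n_frames == 1
        np.testing.assert_allclose(
            grid.frames[0].coordinates, helix.frames[0].coordinates, atol=1e-12
        )

    def test_reextracted_torsions_form_arithmetic_sequence(self, helix):
        from tyrgate.synthetic_data import _resolve_torsion

        spec, moving = _resolve_torsion(helix, (3, "psi"))
        grid = scan_grid(helix, spec, step=2.0, n_steps=10, moving=moving)
        coords = grid.coordinate_array()
        angles = torsion_angles(
            coords[:, spec.i], coords[:, spec.j], coords[:, spec.k], coords[:, spec.l]
        )
        diffs = (np.diff(angles) + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(diffs, 2.0, atol=1e-9)
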