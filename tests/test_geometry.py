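"""Axis fitting, the signed crossing angle, and Kabsch superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from helixpack import synthetic as syn
from helixpack.core import select
from helixpack.geometry import (
    HelixAxis,
    crossing_geometry,
    fit_helix_axis,
    kabsch_superpose,
    rmsd_series,
)

from conftest import SEL_A, SEL_B, rigid_transform


def ideal_ca(n=30):
    return syn.build_ideal_helix(syn.HelixSpec(n_residues=n, cbeta=False)).coords


def angle_between(u, v):
    return np.degrees(np.arccos(np.clip(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


class TestFitHelixAxis:
    def test_ideal_helix_axis_is_z(self):
        ax = fit_helix_axis(ideal_ca())
        assert angle_between(ax.direction, np.array([0, 0, 1.0])) < 0.5
        assert ax.direction[2] > 0  # N->C orientation

    def test_equivariance_under_rotation(self):
        R = Rotation.from_euler("xyz", [40, -25, 110], degrees=True).as_matrix()
        ax = fit_helix_axis(ideal_ca() @ R.T)
        assert angle_between(ax.direction, R @ np.array([0, 0, 1.0])) < 0.5

    def test_noise_robustness(self):
        rng = np.random.default_rng(11)
        pts = ideal_ca() + rng.normal(0, 0.3, size=(30, 3))
        ax = fit_helix_axis(pts)
        assert angle_between(ax.direction, np.array([0, 0, 1.0])) < 2.0

    def test_terminal_truncation_stability(self):
        full = fit_helix_axis(ideal_ca())
        trunc = fit_helix_axis(ideal_ca()[1:])
        assert angle_between(full.direction, trunc.direction) < 1.0

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(ValueError):
            fit_helix_axis(ideal_ca()[:4])
        with pytest.raises(ValueError):
            fit_helix_axis(np.zeros((6, 3)))


def make_axis_pair(omega_deg, offset=10.0):
    """Axis A on z; axis B offset along +x and rotated about +x by omega."""
    a = HelixAxis(np.zeros(3), np.array([0, 0, 1.0]), 15.0)
    db = Rotation.from_rotvec(np.radians(omega_deg) * np.array([1.0, 0, 0])).apply(
        [0, 0, 1.0]
    )
    b = HelixAxis(np.array([offset, 0, 0.0]), db, 15.0)
    return a, b


class TestCrossingGeometry:
    def test_parallel_axes_indeterminate(self):
        a, b = make_axis_pair(0.0)
        cg = crossing_geometry(a, b)
        assert cg.omega == pytest.approx(0.0, abs=1e-9)
        assert cg.handedness == "indeterminate"
        assert cg.closest_distance == pytest.approx(10.0)

    @pytest.mark.parametrize("omega", [-60.0, -30.0, -5.0, 5.0, 30.0, 60.0])
    def test_constructed_angle_recovered_exactly(self, omega):
        a, b = make_axis_pair(omega)
        cg = crossing_geometry(a, b)
        assert cg.omega == pytest.approx(omega, abs=1e-6)
        assert cg.handedness == ("RH" if omega < 0 else "LH")

    def test_mirror_image_flips_handedness(self):
        a, b = make_axis_pair(-30.0)
        # reflect through the xy plane (z -> -z); re-orient N->C afterwards
        refl = np.diag([1.0, 1.0, -1.0])
        am = HelixAxis(refl @ a.anchor, -(refl @ a.direction), a.half_length)
        bm = HelixAxis(refl @ b.anchor, -(refl @ b.direction), b.half_length)
        cg = crossing_geometry(am, bm)
        assert cg.omega == pytest.approx(+30.0, abs=1e-6)
        assert cg.handedness == "LH"

    def test_symmetric_under_argument_swap(self):
        a, b = make_axis_pair(-27.0)
        assert crossing_geometry(a, b).omega == pytest.approx(
            crossing_geometry(b, a).omega, abs=1e-9
        )

    def test_magnitude_invariant_under_rigid_transform(self):
        rng = np.random.default_rng(7)
        a, b = make_axis_pair(-30.0)
        for _ in range(10):
            R, t = rigid_transform(rng)
            at = HelixAxis(R @ a.anchor + t, R @ a.direction, a.half_length)
            bt = HelixAxis(R @ b.anchor + t, R @ b.direction, b.half_length)
            cg = crossing_geometry(at, bt)
            assert cg.omega == pytest.approx(-30.0, abs=1e-6)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        omega=st.floats(-85.0, 85.0).filter(lambda x: abs(x) > 3.0),
        euler=st.tuples(st.floats(-180, 180), st.floats(-89, 89), st.floats(-180, 180)),
        shift=st.tuples(st.floats(-30, 30), st.floats(-30, 30), st.floats(-30, 30)),
    )
    def test_signed_angle_rigid_invariance_property(self, omega, euler, shift):
        a, b = make_axis_pair(omega)
        R = Rotation.from_euler("xyz", euler, degrees=True).as_matrix()
        t = np.asarray(shift)
        at = HelixAxis(R @ a.anchor + t, R @ a.direction, a.half_length)
        bt = HelixAxis(R @ b.anchor + t, R @ b.direction, b.half_length)
        cg = crossing_geometry(at, bt)
        assert cg.omega == pytest.approx(omega, abs=1e-6)
        assert cg.handedness == ("RH" if omega < 0 else "LH")

    def test_antiparallel_direction_convention_consistent(self):
        # flipping one axis's N->C direction must not change the sign
        a, b = make_axis_pair(-30.0)
        b_flipped = HelixAxis(b.anchor, -b.direction, b.half_length)
        assert crossing_geometry(a, b_flipped).omega == pytest.approx(-30.0, abs=1e-6)


def brute_force_min_rmsd(mobile, reference, n_starts=40):
    """Independent oracle: numerically minimize RMSD over rotation space."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return float(np.sqrt(((mob @ R.T - ref) ** 2).sum(axis=1).mean()))

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-6)

    def test_rigid_copy_rmsd_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3)) * 5
        R, t = rigid_transform(rng)
        sup = kabsch_superpose(pts @ R.T + t, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(sup.apply(pts @ R.T + t), pts, atol=1e-6)

    def test_matches_brute_force_oracle_on_4_points(self):
        rng = np.random.default_rng(3)
        mobile = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [0.5, 0.5, 4.0]])
        perturbed = mobile + rng.normal(0, 0.4, size=mobile.shape)
        sup = kabsch_superpose(mobile, perturbed)
        oracle = brute_force_min_rmsd(mobile, perturbed)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-4)

    def test_never_exceeds_unsuperposed_rmsd_and_is_proper(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=(10, 3)) * 4
            b = rng.normal(size=(10, 3)) * 4
            sup = kabsch_superpose(a, b)
            raw = float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
            assert sup.rmsd <= raw + 1e-9
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_identical_frames_all_zero(self, rh_dimer):
        frames = np.repeat(rh_dimer.coords[None], 6, axis=0)
        from helixpack.core import Trajectory

        traj = Trajectory(rh_dimer, frames)
        series = rmsd_series(traj, rh_dimer, [SEL_A, SEL_B])
        np.testing.assert_allclose(series[:, 1], 0.0, atol=1e-6)

    def test_first_frame_reference_starts_at_zero(self, rh_dimer):
        traj = syn.generate_drift_trajectory(rh_dimer, 2.0, n_frames=8, seed=3)
        series = rmsd_series(traj, traj.frame(0), [SEL_A, SEL_B])
        assert series[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_single_perturbed_frame_matches_kabsch(self, rh_dimer):
        rng = np.random.default_rng(5)
        from helixpack.core import Trajectory, selection_indices

        pert = rh_dimer.coords + rng.normal(0, 0.5, size=rh_dimer.coords.shape)
        traj = Trajectory(rh_dimer, pert[None])
        series = rmsd_series(traj, rh_dimer, SEL_A)
        idx = selection_indices(rh_dimer, SEL_A)
        expect = kabsch_superpose(pert[idx], rh_dimer.coords[idx]).rmsd
        assert series[0, 1] == pytest.approx(expect, abs=1e-9)
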