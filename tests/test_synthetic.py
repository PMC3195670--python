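"""Generators: geometric correctness and construction-truth bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixpack import synthetic as syn
from helixpack.core import select
from helixpack.geometry import crossing_geometry, fit_helix_axis

from conftest import SEL_A, SEL_B


def measured_omega(structure, sel_a=SEL_A, sel_b=SEL_B):
    a = fit_helix_axis(select(structure, sel_a.chain_id, atom_names={"CA"}).coords)
    b = fit_helix_axis(select(structure, sel_b.chain_id, atom_names={"CA"}).coords)
    return crossing_geometry(a, b).omega


class TestIdealHelix:
    def test_axis_is_z(self):
        h = syn.build_ideal_helix(syn.HelixSpec(n_residues=30, cbeta=False))
        ax = fit_helix_axis(h.coords)
        z = np.array([0, 0, 1.0])
        assert np.degrees(np.arccos(ax.direction @ z)) < 0.5

    def test_consecutive_calpha_distance_matches_chord_formula(self):
        spec = syn.HelixSpec(n_residues=30, cbeta=False)
        h = syn.build_ideal_helix(spec)
        d = np.linalg.norm(np.diff(h.coords, axis=0), axis=1)
        chord = math.sqrt(
            spec.rise_per_residue**2
            + (2 * spec.radius * math.sin(math.radians(spec.twist_per_residue / 2))) ** 2
        )
        np.testing.assert_allclose(d, chord, atol=1e-9)
        assert abs(chord - 3.8) < 0.05  # ideal-helix backbone spacing

    def test_axial_extent(self):
        h = syn.build_ideal_helix(syn.HelixSpec(n_residues=30, cbeta=False))
        assert np.ptp(h.coords[:, 2]) == pytest.approx(29 * 1.5, abs=0.05)

    def test_glycines_have_no_cbeta(self, alpha_spec):
        h = syn.build_ideal_helix(alpha_spec)
        by_res = {}
        for a in h.atoms:
            by_res.setdefault(a.residue_number, set()).add(a.atom_name)
        assert by_res[972] == {"CA"} and by_res[976] == {"CA"}
        assert by_res[980] == {"CA", "CB"}

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            syn.HelixSpec(n_residues=4)
        with pytest.raises(ValueError):
            syn.HelixSpec(n_residues=10, sequence="GG")


class TestBuildDimer:
    @pytest.mark.parametrize("omega", [-60, -45, -30, -10, 10, 30, 45, 60])
    def test_crossing_angle_roundtrip(self, alpha_spec, beta_spec, omega):
        d = syn.build_dimer(alpha_spec, beta_spec, syn.DimerSpec(omega_target=omega))
        assert measured_omega(d) == pytest.approx(omega, abs=0.5)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(omega=st.floats(-60.0, 60.0).filter(lambda x: abs(x) > 5.0))
    def test_crossing_angle_roundtrip_property(self, alpha_spec, beta_spec, omega):
        d = syn.build_dimer(alpha_spec, beta_spec, syn.DimerSpec(omega_target=omega))
        assert measured_omega(d) == pytest.approx(omega, abs=0.5)

    def test_sign_convention(self, alpha_spec, beta_spec):
        rh = syn.build_dimer(alpha_spec, beta_spec, syn.DimerSpec(omega_target=-30))
        lh = syn.build_dimer(alpha_spec, beta_spec, syn.DimerSpec(omega_target=+30))
        a = fit_helix_axis(select(rh, "A", atom_names={"CA"}).coords)
        b = fit_helix_axis(select(rh, "B", atom_names={"CA"}).coords)
        assert crossing_geometry(a, b).handedness == "RH"
        a = fit_helix_axis(select(lh, "A", atom_names={"CA"}).coords)
        b = fit_helix_axis(select(lh, "B", atom_names={"CA"}).coords)
        assert crossing_geometry(a, b).handedness == "LH"

    def test_clash_rejected(self, alpha_spec, beta_spec):
        with pytest.raises(ValueError):
            syn.build_dimer(
                alpha_spec, beta_spec, syn.DimerSpec(omega_target=0.1, axis_separation=7.0)
            )


class TestModeEnsemble:
    def test_default_mixture_fractions_and_means(self):
        ens = syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=1000, seed=1))
        omegas = np.array([p["omega_true"] for p in ens.provenance])
        rh_frac = (omegas < -2).mean()
        assert rh_frac == pytest.approx(0.70, abs=0.03)

    def test_single_mode_zero_sd_is_exact(self):
        spec = syn.EnsembleSpec(
            modes=(syn.ModeSpec("RH1", 1.0, -30.0, 0.0, 0.0, 0.0),),
            n_members=20,
            seed=0,
        )
        ens = syn.generate_mode_ensemble(spec)
        for i in range(len(ens)):
            assert measured_omega(ens.members[i]) == pytest.approx(-30.0, abs=0.5)

    def test_provenance_labels_agree_with_sign_classification(self):
        ens = syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=500, seed=4))
        agree = 0
        for p in ens.provenance:
            sign_class = "RH1" if p["omega_true"] < 0 else "LH"
            agree += sign_class == p["mode"]
        assert agree / len(ens) >= 0.99

    def test_deterministic_under_seed(self):
        e1 = syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=10, seed=9))
        e2 = syn.generate_mode_ensemble(syn.default_ensemble_spec(n_members=10, seed=9))
        for a, b in zip(e1.members, e2.members):
            np.testing.assert_array_equal(a.coords, b.coords)


class TestAssemblyTrajectory:
    def test_frame0_separation_exact(self):
        traj = syn.generate_assembly_trajectory(n_frames=20, seed=0)
        a = fit_helix_axis(
            traj.frames[0][
                [i for i, at in enumerate(traj.topology.atoms)
                 if at.chain_id == "A" and at.atom_name == "CA"]
            ]
        )
        b = fit_helix_axis(
            traj.frames[0][
                [i for i, at in enumerate(traj.topology.atoms)
                 if at.chain_id == "B" and at.atom_name == "CA"]
            ]
        )
        sep = np.linalg.norm((a.anchor - b.anchor)[:2])
        assert sep == pytest.approx(60.0, abs=1e-6)

    def test_zero_step_no_bind_keeps_separation(self, sel_a, sel_b):
        from helixpack.stability import axis_separation_series, detect_dimerization

        traj = syn.generate_assembly_trajectory(
            step_sd=0.0, tilt_sd=0.0, n_frames=30, seed=1
        )
        d = axis_separation_series(traj, sel_a, sel_b)
        np.testing.assert_allclose(d, 60.0, atol=1e-6)
        ev = detect_dimerization(traj, sel_a, sel_b)
        assert ev.event_time == "none"

    def test_bind_frame_is_honoured(self, sel_a, sel_b):
        from helixpack.stability import detect_dimerization

        traj = syn.generate_assembly_trajectory(n_frames=200, bind_frame=120, seed=6)
        ev = detect_dimerization(traj, sel_a, sel_b)
        assert ev.first_contact_frame == 120
        assert ev.stable_from_frame == 120


class TestDriftTrajectory:
    def test_zero_terminal_zero_noise_is_static(self, rh_dimer, sel_a, sel_b):
        from helixpack.geometry import rmsd_series

        traj = syn.generate_drift_trajectory(rh_dimer, 0.0, n_frames=12, noise_sd=0.0, seed=0)
        series = rmsd_series(traj, traj.frame(0), [sel_a, sel_b])
        np.testing.assert_allclose(series[:, 1], 0.0, atol=1e-6)

    def test_terminal_rmsd_calibrated(self, rh_dimer):
        from helixpack.core import HelixSelector
        from helixpack.geometry import rmsd_series

        traj = syn.generate_drift_trajectory(
            rh_dimer, 4.0, n_frames=20, mode="ramp", noise_sd=0.0, seed=2
        )
        # calibration targets the all-atom superposed RMSD
        all_atoms = [
            HelixSelector("A", (963, 986), ("CA", "CB")),
            HelixSelector("B", (692, 714), ("CA", "CB")),
        ]
        series = rmsd_series(traj, traj.frame(0), all_atoms)
        assert series[-1, 1] == pytest.approx(4.0, abs=1e-3)


class TestRotationScan:
    def test_increment_between_successive_members(self, rh_dimer):
        ens = syn.generate_rotation_scan(rh_dimer, increment=15.0, n=5, helix="B")
        # track one marker atom's azimuth about the fitted B axis
        axis = fit_helix_axis(select(rh_dimer, "B", atom_names={"CA"}).coords)
        marker = [a.key() for a in rh_dimer.atoms].index(("B", 692, "CA"))

        def azimuth(s):
            v = s.coords[marker] - axis.anchor
            v -= (v @ axis.direction) * axis.direction
            e1 = np.array([1.0, 0, 0]) - axis.direction[0] * axis.direction
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis.direction, e1)
            return math.degrees(math.atan2(v @ e2, v @ e1))

        az = [azimuth(m) for m in ens.members]
        steps = [(az[i + 1] - az[i]) % 360 for i in range(4)]
        np.testing.assert_allclose(steps, 15.0, atol=1e-9)

    def test_full_turn_closes(self, rh_dimer):
        ens = syn.generate_rotation_scan(rh_dimer, increment=15.0, n=25, helix="B")
        np.testing.assert_allclose(ens.members[24].coords, rh_dimer.coords, atol=1e-6)

    def test_other_helix_untouched(self, rh_dimer):
        ens = syn.generate_rotation_scan(rh_dimer, increment=15.0, n=4, helix="B")
        mask = [a.chain_id == "A" for a in rh_dimer.atoms]
        for m in ens.members:
            np.testing.assert_array_equal(m.coords[mask], rh_dimer.coords[mask])
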