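"""Kabsch superposition, RMSD series, average structures and flexibility maps."""

import numpy as np
import pytest

from actraj.model_io import SelectionSpec, Structure, Trajectory
from actraj.superpose import (
    DegenerateGeometryError,
    InsufficientFramesError,
    PerResidueProfile,
    ProfileKeyMismatchError,
    average_structure,
    displacement_map,
    kabsch,
    profile_difference,
    rmsd_series,
    rmsf_per_atom,
    rmsf_profile,
)
from actraj.synthetic import make_ideal_helix, make_multistate_trajectory

from conftest import point_structure, random_rotation
from oracles import grid_search_rmsd

ALL = SelectionSpec()
BACKBONE = SelectionSpec(atom_class="backbone")


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        res = kabsch(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        rot_z90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = ref @ rot_z90.T + np.array([5.0, 5.0, 5.0])
        res = kabsch(mobile, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.transform(mobile), ref, atol=1e-9)

    def test_three_point_case_matches_grid_oracle(self):
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        mobile = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.3, 0.0]])
        assert kabsch(mobile, ref).rmsd == pytest.approx(grid_search_rmsd(mobile, ref), abs=1e-3)

    def test_never_exceeds_unfitted_rmsd_and_is_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(size=(10, 3)) * 3
            b = a + rng.normal(size=(10, 3))
            fitted = kabsch(a, b).rmsd
            unfitted = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert fitted <= unfitted + 1e-12
            assert abs(fitted - kabsch(b, a).rmsd) < 1e-9

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a * np.array([-1.0, 1.0, 1.0])  # a mirror image
        res = kabsch(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)


class TestRmsdSeries:
    @pytest.fixture()
    def noisy_traj(self):
        helix = make_ideal_helix(10)
        traj, _ = make_multistate_trajectory(
            [helix], occupancies=[1.0], n_frames=12, noise_sigma=0.3, dt_ns=1.0, seed=5
        )
        return traj

    def test_static_trajectory_all_zero(self):
        helix = make_ideal_helix(8)
        traj = Trajectory(helix, np.repeat(helix.coords[None], 5, axis=0), dt_ns=1.0)
        series = rmsd_series(traj, BACKBONE, reference=helix)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-9)

    def test_reference_frame_zero_gives_zero_first_value(self, noisy_traj):
        series = rmsd_series(noisy_traj, BACKBONE, reference=noisy_traj.frame_structure(0))
        assert series["rmsd"][0] == pytest.approx(0.0, abs=1e-9)

    def test_equals_per_frame_kabsch_oracle(self, noisy_traj):
        ref = noisy_traj.frame_structure(3)
        series = rmsd_series(noisy_traj, BACKBONE, reference=ref)
        idx = np.array([i for i, a in enumerate(noisy_traj.topology.atoms)
                        if a.name in ("N", "CA", "C", "O")])
        for f in range(noisy_traj.n_frames):
            expected = kabsch(noisy_traj.frames[f][idx], ref.coords[idx]).rmsd
            assert series["rmsd"][f] == pytest.approx(expected, abs=1e-12)

    def test_independent_fit_and_measure_selections(self, noisy_traj):
        fit = SelectionSpec.parse("resid=1-5; atoms=backbone")
        measure = SelectionSpec.parse("resid=6-10; atoms=backbone")
        ref = noisy_traj.frame_structure(0)
        series = rmsd_series(noisy_traj, fit, reference=ref, measure_sel=measure)
        assert series["rmsd"][0] == pytest.approx(0.0, abs=1e-9)
        assert (series["rmsd"][1:] > 0).all()


class TestAverageStructure:
    def test_fixed_point_on_identical_frames(self):
        helix = make_ideal_helix(8)
        traj = Trajectory(helix, np.repeat(helix.coords[None], 4, axis=0), dt_ns=1.0)
        avg = average_structure(traj, BACKBONE)
        np.testing.assert_allclose(avg.coords, helix.coords, atol=1e-9)

    def test_rigid_rotated_frames_average_to_template(self):
        helix = make_ideal_helix(8)
        rot = random_rotation(np.random.default_rng(2))
        frames = np.stack([helix.coords, helix.coords @ rot.T + 3.0])
        traj = Trajectory(helix, frames, dt_ns=1.0)
        avg = average_structure(traj, ALL)
        idx = np.arange(len(helix))
        assert kabsch(avg.coords[idx], helix.coords[idx]).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_large_n_recovers_template(self):
        # law of large numbers: sigma=0.1 Å, 500 frames -> mean within 0.02 Å
        helix = make_ideal_helix(10)
        traj, _ = make_multistate_trajectory(
            [helix], occupancies=[1.0], n_frames=500, noise_sigma=0.1, dt_ns=1.0, seed=11
        )
        avg = average_structure(traj, ALL)
        assert kabsch(avg.coords, helix.coords).rmsd < 0.02


class TestRmsf:
    def test_static_trajectory_zero_everywhere(self):
        helix = make_ideal_helix(8)
        traj = Trajectory(helix, np.repeat(helix.coords[None], 3, axis=0), dt_ns=1.0)
        profile = rmsf_profile(traj, BACKBONE)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        helix = make_ideal_helix(8)
        traj = Trajectory(helix, helix.coords[None], dt_ns=1.0)
        with pytest.raises(InsufficientFramesError):
            rmsf_profile(traj, BACKBONE)

    def test_mobile_residue_dominates_profile(self):
        # one residue jitters (sigma 0.5), the rest are frozen
        helix = make_ideal_helix(10)
        rng = np.random.default_rng(4)
        mobile_idx = [i for i, a in enumerate(helix.atoms) if a.residue_number == 5]
        frames = np.repeat(helix.coords[None], 300, axis=0)
        frames[:, mobile_idx, :] += rng.normal(0, 0.5, size=(300, len(mobile_idx), 3))
        traj = Trajectory(helix, frames, dt_ns=1.0)
        profile = rmsf_profile(traj, BACKBONE)
        assert profile.keys[int(np.argmax(profile.values))] == ("A", 5)

    def test_rigid_motion_invariance(self):
        helix = make_ideal_helix(8)
        traj, _ = make_multistate_trajectory(
            [helix], occupancies=[1.0], n_frames=40, noise_sigma=0.2, dt_ns=1.0, seed=9
        )
        rng = np.random.default_rng(10)
        moved = np.stack(
            [f @ random_rotation(rng).T + rng.normal(size=3) * 5 for f in traj.frames]
        )
        base = rmsf_per_atom(traj, BACKBONE)
        shifted = rmsf_per_atom(Trajectory(helix, moved, dt_ns=1.0), BACKBONE)
        np.testing.assert_allclose(base, shifted, atol=1e-6)


class TestProfiles:
    def _profile(self, values):
        keys = tuple(("A", i + 1) for i in range(len(values)))
        return PerResidueProfile(keys=keys, values=np.asarray(values, dtype=float))

    def test_self_difference_and_antisymmetry(self):
        a = self._profile([0.1, 0.5, 0.9])
        b = self._profile([0.2, 0.3, 1.0])
        np.testing.assert_allclose(profile_difference(a, a).values, 0.0)
        total = profile_difference(a, b).values + profile_difference(b, a).values
        np.testing.assert_allclose(total, 0.0, atol=1e-15)

    def test_planted_elementwise_subtraction(self):
        a = self._profile([1.0, 2.0, 3.0])
        b = self._profile([0.5, 2.5, 1.0])
        np.testing.assert_allclose(profile_difference(a, b).values, [0.5, -0.5, 2.0])

    def test_key_mismatch_lists_difference(self):
        a = self._profile([1.0, 2.0])
        b = PerResidueProfile(keys=(("A", 1), ("B", 9)), values=np.array([1.0, 2.0]))
        with pytest.raises(ProfileKeyMismatchError, match="B"):
            profile_difference(a, b)


class TestDisplacementMap:
    def test_identical_and_rotated_structures_are_zero(self):
        helix = make_ideal_helix(10)
        np.testing.assert_allclose(displacement_map(helix, helix, BACKBONE).values, 0.0, atol=1e-9)
        rot = random_rotation(np.random.default_rng(6))
        rotated = helix.with_coords(helix.coords @ rot.T + 2.0)
        np.testing.assert_allclose(
            displacement_map(helix, rotated, BACKBONE).values, 0.0, atol=1e-6
        )

    def test_translated_loop_recovered(self):
        # residues 8-10 moved 3 Å; fit on the untouched residues 1-7
        helix = make_ideal_helix(10)
        coords = helix.coords.copy()
        loop = [i for i, a in enumerate(helix.atoms) if a.residue_number >= 8]
        coords[loop] += np.array([3.0, 0.0, 0.0])
        moved = helix.with_coords(coords)
        fit = SelectionSpec.parse("resid=1-7; atoms=backbone")
        profile = displacement_map(helix, moved, fit)
        for key, value in zip(profile.keys, profile.values):
            if key[1] >= 8:
                assert value == pytest.approx(3.0, abs=1e-6)
            else:
                assert value == pytest.approx(0.0, abs=1e-6)
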