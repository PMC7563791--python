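"""Contact maps, conserved-contact fractions, persistence and monitors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actraj.contacts import (
    AtomSpec,
    DistanceMonitor,
    MonitorResolutionError,
    UndefinedReferenceError,
    conserved_contact_series,
    contact_map,
    distance_series,
    persistence_table,
)
from actraj.model_io import SelectionSpec, Structure, Trajectory
from actraj.synthetic import make_random_structure, make_two_chain_complex

from conftest import make_atom
from oracles import brute_contact_pairs


def two_residue_structure(separation: float) -> Structure:
    return Structure(
        [
            make_atom(1, 0, 0, 0, chain="A", resnum=1),
            make_atom(2, separation, 0, 0, chain="B", resnum=1),
        ]
    )


def random_two_chain(seed: int, n: int = 100) -> Structure:
    a = make_random_structure(n, box=18.0, min_separation=1.5, seed=seed, chain_id="A")
    b = make_random_structure(n, box=18.0, min_separation=1.5, seed=seed + 1000, chain_id="B")
    b_shift = b.with_coords(b.coords + np.array([6.0, 0.0, 0.0]))
    atoms = a.atoms + [
        make_atom(n + i + 1, *p, chain="B", resnum=i + 1) for i, p in enumerate(b_shift.coords)
    ]
    return Structure(atoms)


class TestContactMap:
    def test_boundary_included_at_4p9(self):
        cm = contact_map(two_residue_structure(4.9), "A", "B", cutoff=5.0)
        assert cm.pairs == frozenset({(("A", 1), ("B", 1))})

    def test_boundary_excluded_at_5p1(self):
        cm = contact_map(two_residue_structure(5.1), "A", "B", cutoff=5.0)
        assert len(cm) == 0

    def test_exact_cutoff_distance_is_a_contact(self):
        cm = contact_map(two_residue_structure(5.0), "A", "B", cutoff=5.0)
        assert len(cm) == 1

    def test_matches_bruteforce_on_random_fixtures(self):
        for seed in range(10):
            s = random_two_chain(seed)
            ia = [i for i, a in enumerate(s.atoms) if a.chain_id == "A"]
            ib = [i for i, a in enumerate(s.atoms) if a.chain_id == "B"]
            fast = contact_map(s, "A", "B", cutoff=5.0).pairs
            brute = brute_contact_pairs(s, ia, ib, 5.0)
            assert fast == brute

    def test_symmetry_up_to_orientation(self):
        s = random_two_chain(3)
        ab = contact_map(s, "A", "B", cutoff=5.0).pairs
        ba = contact_map(s, "B", "A", cutoff=5.0).pairs
        assert ab == frozenset((y, x) for x, y in ba)

    def test_hydrogens_ignored(self):
        atoms = [
            make_atom(1, 0, 0, 0, chain="A", resnum=1),
            make_atom(2, 10, 0, 0, chain="B", resnum=1),
            make_atom(3, 5.0, 0, 0, chain="B", resnum=2, name="H", element="H", vdw=1.0),
        ]
        cm = contact_map(Structure(atoms), "A", "B", cutoff=5.0)
        assert len(cm) == 0  # only a hydrogen is within range

    def test_pseudo_chain_selections(self):
        s = make_two_chain_complex(16, 0.5, seed=1)
        spec_a = SelectionSpec(chains=frozenset("A"))
        spec_b = SelectionSpec(chains=frozenset("B"))
        assert contact_map(s, spec_a, spec_b, cutoff=5.0).pairs == contact_map(
            s, "A", "B", cutoff=5.0
        ).pairs

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_cutoff_monotonicity(self, seed):
        s = random_two_chain(seed % 50, n=40)
        small = contact_map(s, "A", "B", cutoff=4.0).pairs
        large = contact_map(s, "A", "B", cutoff=6.0).pairs
        assert small <= large

    def test_empty_side_rejected(self):
        s = random_two_chain(0, n=10)
        with pytest.raises(ValueError):
            contact_map(s, set(), "B")


class TestConservedContacts:
    def _trajectory(self):
        base = make_two_chain_complex(16, 0.5, seed=2)
        apart = base.with_coords(
            base.coords
            + np.where(
                np.array([a.chain_id == "B" for a in base.atoms])[:, None], [0.0, 0.0, 50.0], 0.0
            )
        )
        frames = np.stack([base.coords, base.coords, apart.coords])
        return Trajectory(base, frames, dt_ns=1.0)

    def test_reference_fraction_is_one_and_bounds(self):
        traj = self._trajectory()
        series = conserved_contact_series(traj, "A", "B", cutoff=5.0)
        assert series["fraction"][0] == 1.0
        assert ((series["fraction"] >= 0) & (series["fraction"] <= 1)).all()

    def test_separated_frame_drops_to_zero(self):
        series = conserved_contact_series(self._trajectory(), "A", "B", cutoff=5.0)
        assert series["fraction"].iloc[-1] == 0.0
        assert series["n_contacts"].iloc[-1] == 0

    def test_half_broken_contacts_give_half_fraction(self):
        # chain B atoms split: half stay, half pulled far away at frame 1
        base = make_two_chain_complex(16, 0.5, seed=4)
        ref = contact_map(base, "A", "B", cutoff=5.0)
        b_res = sorted(r for _, r in {p[1] for p in ref.pairs})
        broken = set(b_res[: len(b_res) // 2])
        coords = base.coords.copy()
        for i, a in enumerate(base.atoms):
            if a.chain_id == "B" and a.residue_number in broken:
                coords[i] += np.array([0.0, 0.0, 60.0])
        traj = Trajectory(base, np.stack([base.coords, coords]), dt_ns=1.0)
        series = conserved_contact_series(traj, "A", "B", cutoff=5.0)
        surviving = {p for p in ref.pairs if p[1][1] not in broken}
        assert series["fraction"][1] == pytest.approx(len(surviving) / len(ref.pairs))

    def test_empty_reference_rejected(self):
        base = make_two_chain_complex(9, 40.0, seed=5)
        traj = Trajectory(base, base.coords[None], dt_ns=1.0)
        with pytest.raises(UndefinedReferenceError):
            conserved_contact_series(traj, "A", "B", cutoff=5.0)


class TestPersistence:
    def test_static_complex_all_fractions_one(self):
        base = make_two_chain_complex(16, 0.5, seed=6)
        traj = Trajectory(base, np.repeat(base.coords[None], 4, axis=0), dt_ns=1.0)
        table = persistence_table(traj, "A", "B", cutoff=5.0)
        assert set(table.pair_fraction.values()) == {1.0}
        assert set(table.residue_fraction.values()) == {1.0}
        assert len(table.persistent_residues) == len(table.residue_fraction)

    def test_planted_schedule_recovered_exactly(self):
        # a two-atom interface present in frames 0-4 of 10 -> fraction 0.5
        near = two_residue_structure(4.0)
        far = two_residue_structure(30.0)
        frames = np.stack([near.coords] * 5 + [far.coords] * 5)
        traj = Trajectory(near, frames, dt_ns=1.0)
        table = persistence_table(traj, "A", "B", cutoff=5.0, threshold=0.8)
        assert table.pair_fraction[(("A", 1), ("B", 1))] == 0.5
        assert table.persistent_residues == ()

    def test_threshold_boundary_is_strict(self):
        # present in exactly 8 of 10 frames -> fraction 0.8, NOT persistent
        near = two_residue_structure(4.0)
        far = two_residue_structure(30.0)
        frames = np.stack([near.coords] * 8 + [far.coords] * 2)
        traj = Trajectory(near, frames, dt_ns=1.0)
        table = persistence_table(traj, "A", "B", cutoff=5.0, threshold=0.8)
        assert table.residue_fraction[("A", 1)] == pytest.approx(0.8)
        assert table.persistent_residues == ()
        above = persistence_table(
            Trajectory(near, np.stack([near.coords] * 9 + [far.coords]), dt_ns=1.0),
            "A",
            "B",
            cutoff=5.0,
            threshold=0.8,
        )
        assert ("A", 1) in above.persistent_residues


class TestMonitors:
    def test_three_four_five(self):
        s = Structure(
            [
                make_atom(1, 0, 0, 0, chain="A", resnum=1),
                make_atom(2, 3, 4, 0, chain="B", resnum=1),
            ]
        )
        traj = Trajectory(s, s.coords[None], dt_ns=1.0)
        mon = DistanceMonitor(label="d", spec_a=AtomSpec("A", 1, "CA"), spec_b=AtomSpec("B", 1, "CA"))
        table = distance_series(traj, [mon])
        assert table["d"][0] == pytest.approx(5.0)

    def test_scripted_separation_ramp(self):
        s = two_residue_structure(3.0)
        ramp = np.linspace(3.0, 9.0, 7)
        frames = np.stack(
            [np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]) for d in ramp]
        )
        traj = Trajectory(s, frames, dt_ns=1.0)
        mon = DistanceMonitor.parse("sep: A:GLY:1:CA -- B:GLY:1:CA")
        table = distance_series(traj, [mon])
        np.testing.assert_allclose(table["sep"], ramp, atol=1e-6)
        np.testing.assert_allclose(mon.series, ramp, atol=1e-6)

    def test_static_trajectory_constant_series(self):
        s = two_residue_structure(4.2)
        traj = Trajectory(s, np.repeat(s.coords[None], 3, axis=0), dt_ns=1.0)
        table = distance_series(traj, [DistanceMonitor.parse("d: A:GLY:1:CA -- B:GLY:1:CA")])
        np.testing.assert_allclose(table["d"], 4.2)

    def test_unresolved_spec_names_monitor(self):
        s = two_residue_structure(4.2)
        traj = Trajectory(s, s.coords[None], dt_ns=1.0)
        mon = DistanceMonitor.parse("bad: A:LYS:99:NZ -- B:GLY:1:CA")
        with pytest.raises(MonitorResolutionError, match="A:LYS:99:NZ"):
            distance_series(traj, [mon])

    def test_parse_formats(self):
        mon = DistanceMonitor.parse("k1065: A:LYS:1065:NZ -- B:ATP:1:O2G")
        assert mon.label == "k1065"
        assert mon.spec_a == AtomSpec("A", 1065, "NZ", "LYS")
        assert mon.spec_b == AtomSpec("B", 1, "O2G", "ATP")
        short = DistanceMonitor.parse("d: A:5:CA -- B:7:CB")
        assert short.spec_a.residue_name is None
        with pytest.raises(ValueError):
            DistanceMonitor.parse("no separator here")
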