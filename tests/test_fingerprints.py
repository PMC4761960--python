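import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cntkit.builder import merge_structures
from cntkit.fingerprints import (
    ContactCriteria,
    FingerprintError,
    HBondCriteria,
    SaltBridgeCriteria,
    StackingCriteria,
    aromatic_rings,
    contact_count,
    contact_ratio_table,
    detect_hbonds,
    detect_pi_stacking,
    detect_salt_bridges,
    residue_selections,
    stacking_formation_ratio,
)
from cntkit.model import Selection, Structure, Trajectory
from cntkit.synthetic import Event, ScenarioSpec, generate_scenario

from conftest import make_structure
from oracles import (
    brute_contact_count,
    brute_hbonds,
    brute_salt_bridge_pairs,
    random_rotation,
)

RING_RADIUS = 0.139
PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _sel(indices):
    return Selection(expression="test", resolved=frozenset(indices))


def _pair_structure(d):
    return make_structure(
        [
            ("CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            ("CB", "C", "VAL", 2, "A", (d, 0.0, 0.0)),
        ]
    )


class TestContactCount:
    def test_within_cutoff(self):
        s = _pair_structure(0.30)
        assert contact_count(s, s.positions, _sel([0]), _sel([1])) == 1

    def test_beyond_cutoff(self):
        s = _pair_structure(0.51)
        assert contact_count(s, s.positions, _sel([0]), _sel([1])) == 0

    def test_symmetric(self):
        s = _pair_structure(0.30)
        a, b = _sel([0]), _sel([1])
        assert contact_count(s, s.positions, a, b) == contact_count(s, s.positions, b, a)

    def test_hydrogens_excluded_by_default(self):
        s = make_structure(
            [
                ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
                ("H1", "H", "VAL", 2, "A", (0.2, 0, 0)),
            ]
        )
        assert contact_count(s, s.positions, _sel([0]), _sel([1])) == 0
        loose = ContactCriteria(cutoff=0.5, heavy_only=False)
        assert contact_count(s, s.positions, _sel([0]), _sel([1]), loose) == 1

    def test_empty_selection_is_error(self):
        s = _pair_structure(0.3)
        with pytest.raises(FingerprintError, match="non-empty"):
            contact_count(s, s.positions, _sel([]), _sel([1]))

    def test_overlapping_selections_are_error(self):
        s = _pair_structure(0.3)
        with pytest.raises(FingerprintError, match="disjoint"):
            contact_count(s, s.positions, _sel([0, 1]), _sel([1]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_frames(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        coords = rng.uniform(-1.0, 1.0, size=(n, 3))
        elements = rng.choice(["C", "H", "O"], size=n)
        s = make_structure(
            [(f"A{i}", elements[i], "UNK", i + 1, "A", coords[i]) for i in range(n)]
        )
        ia, ib = list(range(0, 30)), list(range(30, 60))
        got = contact_count(s, coords, _sel(ia), _sel(ib))
        heavy = [e != "H" for e in elements]
        assert got == brute_contact_count(coords, ia, ib, 0.5, heavy)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_monotone_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-0.8, 0.8, size=(40, 3))
        s = make_structure(
            [(f"A{i}", "C", "UNK", i + 1, "A", coords[i]) for i in range(40)]
        )
        ia, ib = _sel(range(20)), _sel(range(20, 40))
        counts = [
            contact_count(s, coords, ia, ib, ContactCriteria(cutoff=c))
            for c in (0.2, 0.4, 0.6, 0.9)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-1, 1, size=(30, 3))
        s = make_structure(
            [(f"A{i}", "C", "UNK", i + 1, "A", coords[i]) for i in range(30)]
        )
        ia, ib = _sel(range(15)), _sel(range(15, 30))
        before = contact_count(s, coords, ia, ib)
        moved = coords @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        assert contact_count(s, moved, ia, ib) == before


class TestContactRatioTable:
    def _trajectory(self, contact_frames, n_frames=10):
        s = make_structure(
            [
                ("CA", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
                ("O1", "O", "CBX", 2, "A", (5.0, 0.0, 0.0)),
            ]
        )
        frames = np.zeros((n_frames, 2, 3))
        frames[:, 1, 0] = 5.0
        for k in contact_frames:
            frames[k, 1, 0] = 0.3
        return Trajectory(topology=s, times=np.arange(n_frames, dtype=float), frames=frames)

    def test_six_of_ten_flagged_persistent(self):
        traj = self._trajectory(range(6))
        probes = residue_selections(traj.topology, [("A", 1, "ALA")])
        table = contact_ratio_table(traj, probes, _sel([1]))
        assert table.rows[0].fraction == pytest.approx(0.6)
        assert table.rows[0].persistent

    def test_never_in_contact(self):
        traj = self._trajectory([])
        probes = residue_selections(traj.topology, [("A", 1, "ALA")])
        table = contact_ratio_table(traj, probes, _sel([1]))
        assert table.rows[0].fraction == 0.0
        assert not table.rows[0].persistent

    def test_scripted_55_percent(self):
        spec = ScenarioSpec(
            n_frames=100,
            events=(Event("salt_bridge", "LYS3", 0, 55),),
        )
        traj, _, _ = generate_scenario(spec)
        s = traj.topology
        key = next(k for k in s.residues() if k[2] == "LYS")
        probes = residue_selections(s, [key])
        partner = Selection("carboxyl", s.groups["carboxyl"])
        table = contact_ratio_table(traj, probes, partner)
        assert table.rows[0].fraction == pytest.approx(0.55)
        assert table.rows[0].persistent


class TestHydrogenBonds:
    def _linear(self, d_no, angle_deg):
        # N at origin, H at 0.1 nm along x, O placed to give the D-H...A angle
        theta = math.radians(180.0 - angle_deg)
        h = np.array([0.1, 0.0, 0.0])
        oa = h + (d_no - 0.1) * np.array([math.cos(theta), math.sin(theta), 0.0])
        return make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0, 0, 0)),
                ("H", "H", "GLY", 1, "A", h),
                ("O1", "O", "CBX", 2, "A", oa),
            ]
        )

    def test_linear_bond_detected(self):
        s = self._linear(0.29, 180.0)
        found = detect_hbonds(s, s.positions, _sel([0]), _sel([2]))
        assert found == [(0, 1, 2)]

    def test_bent_geometry_rejected(self):
        s = self._linear(0.29, 120.0)
        assert detect_hbonds(s, s.positions, _sel([0]), _sel([2])) == []

    def test_long_distance_rejected(self):
        s = self._linear(0.40, 180.0)
        assert detect_hbonds(s, s.positions, _sel([0]), _sel([2])) == []

    def test_donor_without_hydrogen_suggests_map(self):
        s = make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0, 0, 0)),
                ("O1", "O", "CBX", 2, "A", (0.29, 0, 0)),
            ]
        )
        with pytest.raises(FingerprintError, match="hydrogen_map"):
            detect_hbonds(s, s.positions, _sel([0]), _sel([1]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        entries = []
        donor_h = []
        # 10 donor residues (N + attached H), 10 lone acceptors
        for r in range(10):
            n_pos = rng.uniform(-0.6, 0.6, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            entries.append(("N", "N", "GLY", r + 1, "A", n_pos))
            entries.append(("H", "H", "GLY", r + 1, "A", n_pos + 0.1 * direction))
        for r in range(10):
            entries.append(("O1", "O", "CBX", 100 + r, "A", rng.uniform(-0.6, 0.6, 3)))
        s = make_structure(entries)
        coords = s.positions
        donors = [i for i, a in enumerate(s.atoms) if a.name == "N"]
        hmap = {d: [d + 1] for d in donors}
        acceptors = [i for i, a in enumerate(s.atoms) if a.name == "O1"]
        got = set(detect_hbonds(s, coords, _sel(donors), _sel(acceptors), hydrogen_map=hmap))
        expected = brute_hbonds(coords, [(d, [d + 1]) for d in donors], acceptors, 0.35, 150.0)
        assert got == expected


class TestSaltBridges:
    def _pair(self, d):
        s = make_structure(
            [
                ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
                ("O1", "O", "CBX", 2, "A", (d, 0, 0)),
            ]
        )
        charges = np.array([1.0, -0.5])
        return s, charges

    def test_close_pair_is_bridge(self):
        s, q = self._pair(0.32)
        out = detect_salt_bridges(s, s.positions, _sel([0]), _sel([1]), charges=q)
        assert len(out) == 1
        (ckey, akey, dist) = out[0]
        assert ckey[2] == "LYS" and akey[2] == "CBX"
        assert dist == pytest.approx(0.32)

    def test_distant_pair_is_not(self):
        s, q = self._pair(0.60)
        assert detect_salt_bridges(s, s.positions, _sel([0]), _sel([1]), charges=q) == []

    def test_requires_charge_annotations(self):
        s, _ = self._pair(0.32)
        with pytest.raises(FingerprintError, match="charge"):
            detect_salt_bridges(s, s.positions, _sel([0]), _sel([1]))

    def test_one_entry_per_residue_pair_min_distance(self):
        s = make_structure(
            [
                ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
                ("O1", "O", "CBX", 2, "A", (0.35, 0, 0)),
                ("O2", "O", "CBX", 2, "A", (0.30, 0, 0)),
            ]
        )
        q = np.array([1.0, -0.5, -0.5])
        out = detect_salt_bridges(s, s.positions, _sel([0]), _sel([1, 2]), charges=q)
        assert len(out) == 1
        assert out[0][2] == pytest.approx(0.30)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        entries = []
        for r in range(12):
            entries.append(("NZ", "N", "LYS", r + 1, "A", rng.uniform(-0.7, 0.7, 3)))
        for r in range(12):
            entries.append(("O1", "O", "CBX", 50 + r, "A", rng.uniform(-0.7, 0.7, 3)))
        s = make_structure(entries)
        coords = s.positions
        q = np.array([1.0] * 12 + [-0.5] * 12)
        cats, anis = list(range(12)), list(range(12, 24))
        got = detect_salt_bridges(s, coords, _sel(cats), _sel(anis), charges=q)
        # every atom is its own residue, so pairs map 1:1 onto the oracle
        expected = brute_salt_bridge_pairs(coords, cats, anis, 0.4)
        got_pairs = {
            (c[1] - 1, 50 + a[1] - 50 + 12 - 0): d for c, a, d in got
        }
        assert len(got) == len(expected)
        for ckey, akey, d in got:
            c_idx = ckey[1] - 1
            a_idx = 12 + (akey[1] - 50)
            assert (c_idx, a_idx) in expected
            assert d == pytest.approx(expected[(c_idx, a_idx)])


def _tube_frame_info(tube):
    coords = tube.structure.positions
    cents = np.array([coords[list(h)].mean(axis=0) for h in tube.lattice.hexagons])
    return coords, cents


def _hexagon_normal(cent):
    radial = np.array([cent[0], cent[1], 0.0])
    return radial / np.linalg.norm(radial)


def _ring_entries(center, e1, e2, resid=50):
    entries = []
    for k, name in enumerate(PHE_RING):
        theta = math.radians(60.0 * k)
        pos = center + RING_RADIUS * (math.cos(theta) * e1 + math.sin(theta) * e2)
        entries.append((name, "C", "PHE", resid, "A", pos))
    return entries


class TestPiStacking:
    def _merged(self, small_tube, center, e1, e2):
        ring = make_structure(_ring_entries(center, e1, e2))
        merged, _ = merge_structures(small_tube.structure, ring)
        return merged

    def _mid_hexagon(self, small_tube):
        coords, cents = _tube_frame_info(small_tube)
        mid = cents[np.argmin(np.abs(cents[:, 2]))]
        return mid, _hexagon_normal(mid)

    def test_parallel_configuration(self, small_tube):
        hc, nrm = self._mid_hexagon(small_tube)
        z = np.array([0.0, 0.0, 1.0])
        merged = self._merged(small_tube, hc + 0.35 * nrm, z, np.cross(nrm, z))
        events = detect_pi_stacking(
            merged, merged.positions, aromatic_rings(merged), small_tube.lattice
        )
        assert len(events) == 1
        ev = events[0]
        assert ev.cls == "parallel"
        assert ev.ring_centroid_distance == pytest.approx(0.35, abs=1e-6)
        assert ev.interplanar_angle <= 1.0

    def test_tshape_configuration(self, small_tube):
        hc, nrm = self._mid_hexagon(small_tube)
        z = np.array([0.0, 0.0, 1.0])
        merged = self._merged(small_tube, hc + 0.50 * nrm, nrm, z)
        events = detect_pi_stacking(
            merged, merged.positions, aromatic_rings(merged), small_tube.lattice
        )
        assert len(events) == 1
        assert events[0].cls == "tshape"
        assert events[0].interplanar_angle == pytest.approx(90.0, abs=1.0)

    def test_lateral_offset_gate(self, small_tube):
        # overhang the rim: face-on ring whose centroid is 0.45 nm off any
        # lattice hexagon laterally -> rejected even with a loose distance gate
        coords, cents = _tube_frame_info(small_tube)
        rim_hex = cents[np.argmax(cents[:, 2])]
        nrm = _hexagon_normal(rim_hex)
        z = np.array([0.0, 0.0, 1.0])
        center = rim_hex + 0.35 * nrm + 0.45 * z
        merged = self._merged(small_tube, center, z, np.cross(nrm, z))
        loose = StackingCriteria(parallel_centroid_max=0.8, tshape_centroid_max=0.2)
        events = detect_pi_stacking(
            merged, merged.positions, aromatic_rings(merged), small_tube.lattice, loose
        )
        assert events == []

    def test_far_offset_default_criteria(self, small_tube):
        coords, cents = _tube_frame_info(small_tube)
        rim_hex = cents[np.argmax(cents[:, 2])]
        nrm = _hexagon_normal(rim_hex)
        z = np.array([0.0, 0.0, 1.0])
        center = rim_hex + 0.35 * nrm + 0.5 * z
        merged = self._merged(small_tube, center, z, np.cross(nrm, z))
        events = detect_pi_stacking(
            merged, merged.positions, aromatic_rings(merged), small_tube.lattice
        )
        assert events == []

    def test_rotation_invariance(self, small_tube):
        hc, nrm = self._mid_hexagon(small_tube)
        z = np.array([0.0, 0.0, 1.0])
        merged = self._merged(small_tube, hc + 0.35 * nrm, z, np.cross(nrm, z))
        rng = np.random.default_rng(4)
        rot = random_rotation(rng)
        moved = merged.positions @ rot.T + np.array([3.0, -2.0, 1.0])
        events = detect_pi_stacking(
            merged, moved, aromatic_rings(merged), small_tube.lattice
        )
        assert len(events) == 1 and events[0].cls == "parallel"

    def test_degenerate_ring_is_error(self, small_tube):
        entries = [
            (name, "C", "PHE", 50, "A", (0.01 * k, 0.0, 0.0))
            for k, name in enumerate(PHE_RING)
        ]
        ring = make_structure(entries)
        merged, _ = merge_structures(small_tube.structure, ring)
        with pytest.raises(FingerprintError, match="degenerate"):
            detect_pi_stacking(
                merged, merged.positions, aromatic_rings(merged), small_tube.lattice
            )


class TestStackingFormationRatio:
    def test_scripted_60_of_100(self):
        spec = ScenarioSpec(
            n_frames=100, events=(Event("stack_parallel", "PHE2", 0, 60),)
        )
        traj, _, lattice = generate_scenario(spec)
        key = next(k for k in traj.topology.residues() if k[2] == "PHE")
        ratio = stacking_formation_ratio(traj, key, lattice)
        assert ratio.ratio == pytest.approx(0.60)
        assert ratio.parallel_fraction == pytest.approx(0.60)
        assert ratio.persistent

    def test_never_stacked(self):
        spec = ScenarioSpec(n_frames=20)
        traj, _, lattice = generate_scenario(spec)
        key = next(k for k in traj.topology.residues() if k[2] == "PHE")
        ratio = stacking_formation_ratio(traj, key, lattice)
        assert ratio.ratio == 0.0
        assert not ratio.persistent

    def test_55_percent_exceeds_threshold(self):
        spec = ScenarioSpec(
            n_frames=100, events=(Event("stack_parallel", "PHE2", 0, 55),)
        )
        traj, _, lattice = generate_scenario(spec)
        key = next(k for k in traj.topology.residues() if k[2] == "PHE")
        ratio = stacking_formation_ratio(traj, key, lattice)
        assert ratio.ratio == pytest.approx(0.55)
        assert ratio.persistent  # > the 0.5 persistence benchmark

    def test_non_aromatic_residue_is_error(self):
        spec = ScenarioSpec(n_frames=15)
        traj, _, lattice = generate_scenario(spec)
        key = next(k for k in traj.topology.residues() if k[2] == "LYS")
        with pytest.raises(FingerprintError, match="not aromatic"):
            stacking_formation_ratio(traj, key, lattice)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    cutoff=st.floats(0.1, 1.2),
)
def test_contact_count_equals_oracle_property(seed, cutoff):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    coords = rng.uniform(-1, 1, size=(n, 3))
    s = make_structure(
        [(f"A{i}", "C", "UNK", i + 1, "A", coords[i]) for i in range(n)]
    )
    half = n // 2
    ia, ib = list(range(half)), list(range(half, n))
    got = contact_count(
        s, coords, _sel(ia), _sel(ib), ContactCriteria(cutoff=cutoff)
    )
    assert got == brute_contact_count(coords, ia, ib, cutoff, [True] * n)
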