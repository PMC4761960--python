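import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cntkit.builder import NonbondedParams
from cntkit.energetics import (
    COULOMB_CONSTANT,
    EnergeticsError,
    KJ_PER_KCAL,
    coulomb_pair,
    interaction_energy_series,
    lj_pair,
    rmsd_series,
)
from cntkit.model import Selection, Trajectory
from cntkit.selection import resolve_selection

from conftest import make_structure
from oracles import quaternion_superposition_rmsd, random_rotation

CC = (0.36, 0.34)  # tube carbon epsilon (kJ/mol), sigma (nm)


class TestLJPair:
    def test_well_depth_at_minimum(self):
        r_min = 2 ** (1 / 6) * 0.34
        assert lj_pair(r_min, CC, CC) == pytest.approx(-0.36, abs=1e-12)

    def test_zero_crossing_at_sigma(self):
        assert lj_pair(0.34, CC, CC) == pytest.approx(0.0, abs=1e-12)

    def test_unlike_pair_hand_oracle(self):
        # independent scalar evaluation of the combined formula
        eps = math.sqrt(0.4 * 0.9)
        sig = (0.3 + 0.5) / 2
        r = 0.45
        expected = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert lj_pair(r, (0.4, 0.3), (0.9, 0.5)) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_r_is_error(self):
        with pytest.raises(EnergeticsError):
            lj_pair(0.0, CC, CC)

    @settings(max_examples=50, deadline=None)
    @given(
        e1=st.floats(0.01, 5.0), e2=st.floats(0.01, 5.0),
        s1=st.floats(0.1, 0.6), s2=st.floats(0.1, 0.6),
    )
    def test_minimum_location_and_depth_property(self, e1, e2, s1, s2):
        eps = math.sqrt(e1 * e2)
        sig = 0.5 * (s1 + s2)
        r_min = 2 ** (1 / 6) * sig
        assert lj_pair(r_min, (e1, s1), (e2, s2)) == pytest.approx(-eps, rel=1e-9)
        # nearby points are higher
        assert lj_pair(0.99 * r_min, (e1, s1), (e2, s2)) > -eps
        assert lj_pair(1.01 * r_min, (e1, s1), (e2, s2)) > -eps


class TestCoulombPair:
    def test_unit_charges_at_1nm(self):
        assert coulomb_pair(1.0, 1.0, 1.0) == pytest.approx(138.935458)

    def test_zero_charge(self):
        assert coulomb_pair(0.5, 0.0, 1.0) == 0.0

    def test_symmetry(self):
        assert coulomb_pair(0.7, 0.3, -0.8) == coulomb_pair(0.7, -0.8, 0.3)

    def test_nonpositive_r_is_error(self):
        with pytest.raises(EnergeticsError):
            coulomb_pair(-0.1, 1.0, 1.0)


def _two_atom_trajectory(separations):
    s = make_structure(
        [
            ("C", "C", "CNT", 1, "X", (0, 0, 0)),
            ("O", "O", "CBX", 2, "X", (1, 0, 0)),
        ]
    )
    frames = np.zeros((len(separations), 2, 3))
    frames[:, 1, 0] = separations
    traj = Trajectory(topology=s, times=np.arange(len(separations), dtype=float), frames=frames)
    params = NonbondedParams(
        epsilon=np.array([0.36, 0.65]),
        sigma=np.array([0.34, 0.296]),
        charge=np.array([0.2, -0.5]),
    )
    return traj, params


class TestInteractionEnergySeries:
    def test_matches_closed_form_pair_curves(self):
        separations = np.array([0.3, 0.4, 0.55, 0.8, 0.95])
        traj, params = _two_atom_trajectory(separations)
        series = interaction_energy_series(
            traj, Selection("a", frozenset({0})), Selection("b", frozenset({1})), params
        )
        for k, r in enumerate(separations):
            assert series.vdw[k] == pytest.approx(
                lj_pair(r, (0.36, 0.34), (0.65, 0.296)), rel=1e-12
            )
            assert series.coulomb[k] == pytest.approx(
                coulomb_pair(r, 0.2, -0.5), rel=1e-12
            )

    def test_beyond_cutoff_is_zero(self):
        traj, params = _two_atom_trajectory(np.array([1.5, 2.0]))
        series = interaction_energy_series(
            traj, Selection("a", frozenset({0})), Selection("b", frozenset({1})), params
        )
        assert np.all(series.vdw == 0.0)
        assert np.all(series.coulomb == 0.0)

    def test_kcal_anchor(self):
        assert -502.08 / KJ_PER_KCAL == pytest.approx(-120.0)
        traj, params = _two_atom_trajectory(np.array([0.4]))
        series = interaction_energy_series(
            traj, Selection("a", frozenset({0})), Selection("b", frozenset({1})), params
        )
        assert series.vdw_kcal[0] == pytest.approx(series.vdw[0] / 4.184)

    def test_overlapping_groups_rejected(self):
        traj, params = _two_atom_trajectory(np.array([0.4]))
        with pytest.raises(EnergeticsError, match="overlap"):
            interaction_energy_series(
                traj, Selection("a", frozenset({0, 1})), Selection("b", frozenset({1})), params
            )

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-0.5, 0.5, size=(8, 3))
        s = make_structure(
            [(f"C{i}", "C", "UNK", i + 1, "A", coords[i]) for i in range(8)]
        )
        frames = np.stack([coords, coords @ random_rotation(rng).T + rng.uniform(-3, 3, 3)])
        traj = Trajectory(topology=s, times=[0.0, 1.0], frames=frames)
        params = NonbondedParams(
            epsilon=np.full(8, 0.4), sigma=np.full(8, 0.32), charge=np.linspace(-0.5, 0.5, 8)
        )
        series = interaction_energy_series(
            traj, Selection("a", frozenset(range(4))), Selection("b", frozenset(range(4, 8))), params
        )
        assert series.vdw[1] == pytest.approx(series.vdw[0], rel=1e-9)
        assert series.coulomb[1] == pytest.approx(series.coulomb[0], rel=1e-9)

    def test_cutoff_monotonicity_same_sign_charges(self):
        # charges all positive: |coulomb| can only grow as the cutoff admits
        # more pairs
        rng = np.random.default_rng(11)
        coords = rng.uniform(-1.2, 1.2, size=(10, 3))
        s = make_structure(
            [(f"C{i}", "C", "UNK", i + 1, "A", coords[i]) for i in range(10)]
        )
        traj = Trajectory(topology=s, times=[0.0], frames=coords[None])
        params = NonbondedParams(
            epsilon=np.zeros(10) + 1e-12, sigma=np.full(10, 0.3), charge=np.full(10, 0.3)
        )
        a = Selection("a", frozenset(range(5)))
        b = Selection("b", frozenset(range(5, 10)))
        values = [
            abs(interaction_energy_series(traj, a, b, params, cutoff=c).coulomb[0])
            for c in (0.3, 0.6, 1.0, 2.0, 4.0)
        ]
        assert values == sorted(values)


def _ca_trajectory(frames):
    n = frames.shape[1]
    s = make_structure(
        [("CA", "C", "ALA", i + 1, "A", frames[0, i]) for i in range(n)]
    )
    return Trajectory(topology=s, times=np.arange(len(frames), dtype=float), frames=frames)


class TestRmsdSeries:
    def test_reference_vs_itself_is_zero(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-1, 1, size=(10, 3))
        traj = _ca_trajectory(base[None])
        series = rmsd_series(traj)
        assert series.rmsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motions_removed(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(-1, 1, size=(12, 3))
        frames = [base]
        for _ in range(5):
            frames.append(base @ random_rotation(rng).T + rng.uniform(-10, 10, 3))
        traj = _ca_trajectory(np.stack(frames))
        series = rmsd_series(traj)
        assert np.all(series.rmsd <= 1e-6)

    def test_matches_quaternion_oracle_single_displacement(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(-1, 1, size=(20, 3))
        moved = base.copy()
        moved[7] += np.array([0.25, -0.1, 0.3])
        traj = _ca_trajectory(np.stack([base, moved]))
        series = rmsd_series(traj)
        expected = quaternion_superposition_rmsd(moved, base)
        assert series.rmsd[1] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_quaternion_oracle_random_deformations(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(-1, 1, size=(15, 3))
        frames = [base]
        for _ in range(4):
            deformed = base + rng.normal(0, 0.05, base.shape)
            frames.append(deformed @ random_rotation(rng).T + rng.uniform(-2, 2, 3))
        traj = _ca_trajectory(np.stack(frames))
        series = rmsd_series(traj)
        for k in range(1, 5):
            expected = quaternion_superposition_rmsd(traj.frames[k], base)
            assert series.rmsd[k] == pytest.approx(expected, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(-1, 1, size=(9, 3))
        moved = base + rng.normal(0, 0.1, base.shape)
        perm = rng.permutation(9)
        traj1 = _ca_trajectory(np.stack([base, moved]))
        traj2 = _ca_trajectory(np.stack([base[perm], moved[perm]]))
        r1 = rmsd_series(traj1).rmsd[1]
        r2 = rmsd_series(traj2).rmsd[1]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_fewer_than_three_atoms_is_error(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(-1, 1, size=(5, 3))
        traj = _ca_trajectory(base[None])
        with pytest.raises(EnergeticsError, match=">=3"):
            rmsd_series(traj, selection=Selection("two", frozenset({0, 1})))

    def test_default_selection_is_calpha(self):
        entries = [
            ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
            ("CB", "C", "ALA", 1, "A", (0.15, 0, 0)),
            ("CA", "C", "GLY", 2, "A", (0.4, 0, 0)),
            ("CA", "C", "VAL", 3, "A", (0.8, 0.3, 0)),
        ]
        s = make_structure(entries)
        frames = np.stack([s.positions, s.positions])
        frames[1, 1] += 5.0  # move only the non-CA atom
        traj = Trajectory(topology=s, times=[0.0, 1.0], frames=frames)
        series = rmsd_series(traj)
        assert series.rmsd[1] == pytest.approx(0.0, abs=1e-12)
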