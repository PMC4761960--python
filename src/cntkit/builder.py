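"""Armchair nanotube construction, edge carboxylation, nonbonded parameters
and rigid posing of tube + protein systems.

The tube is built on a cylinder about the z axis.  Rolling the flat honeycomb
sheet by arc length turns C-C bonds into chords, which shortens them by at
most ~0.7% for n=12; this is the standard builder convention and is left
uncorrected (bond-length fidelity is not used downstream).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, Structure, StructureError
from .selection import resolve_selection

__all__ = [
    "NanotubeSpec",
    "NonbondedParams",
    "BuiltTube",
    "TubeLattice",
    "BuilderError",
    "ParameterError",
    "build_armchair_swcnt",
    "carboxylate_edges",
    "assign_nonbonded_params",
    "pose_system",
    "merge_structures",
    "find_hexagons",
    "write_build_report",
    "write_parameter_sidecar",
    "PARAMETER_TABLES",
]


class BuilderError(ValueError):
    """Invalid nanotube specification or posing failure."""


class ParameterError(ValueError):
    """Nonbonded parameter assignment failure."""


@dataclass(frozen=True)
class NanotubeSpec:
    """Recipe for an armchair (n,n) tube."""

    n: int
    target_length: float  # nm
    cc_bond: float = 0.142  # nm
    carboxyl_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise BuilderError(f"chiral index n must be >= 2, got {self.n}")
        if self.target_length <= 0:
            raise BuilderError("target_length must be positive")
        if self.cc_bond <= 0:
            raise BuilderError("cc_bond must be positive")
        if self.carboxyl_count < 0:
            raise BuilderError("carboxyl_count must be non-negative")
        if self.carboxyl_count > 4 * self.n:
            raise BuilderError(
                f"carboxyl_count {self.carboxyl_count} exceeds rim capacity "
                f"{4 * self.n} (rim capacity exceeded)"
            )

    @property
    def axial_period(self) -> float:
        """Length of one translational unit cell (4n atoms), sqrt(3)*a_cc."""
        return math.sqrt(3.0) * self.cc_bond

    @property
    def diameter_closed_form(self) -> float:
        """Chiral-vector diameter (sqrt(3)*a_cc/pi)*sqrt(3 n^2) = 3 n a_cc / pi."""
        return (math.sqrt(3.0) * self.cc_bond / math.pi) * math.sqrt(3.0 * self.n**2)


@dataclass
class NonbondedParams:
    """Per-atom Lennard-Jones epsilon (kJ/mol), sigma (nm) and charge (e)."""

    epsilon: np.ndarray
    sigma: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        if np.any(self.epsilon < 0):
            raise ParameterError("epsilon must be non-negative")
        if np.any(self.sigma <= 0):
            raise ParameterError("sigma must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.epsilon)


@dataclass(frozen=True)
class TubeLattice:
    """Index-level view of a tube inside some Structure.

    Holds the cnt atom indices, the hexagonal-ring index sets (6-tuples)
    and the rim-ring indices; ``shifted`` re-bases everything after the tube
    is merged into a larger system.
    """

    cnt_indices: tuple[int, ...]
    hexagons: tuple[tuple[int, ...], ...]
    rim_indices: tuple[int, ...]

    def shifted(self, offset: int) -> "TubeLattice":
        return TubeLattice(
            cnt_indices=tuple(i + offset for i in self.cnt_indices),
            hexagons=tuple(tuple(i + offset for i in h) for h in self.hexagons),
            rim_indices=tuple(i + offset for i in self.rim_indices),
        )


@dataclass
class BuiltTube:
    structure: Structure
    spec: NanotubeSpec
    actual_length: float  # nm, tip-to-tip ring span
    diameter: float  # nm, from coordinates: 2 * mean radial distance
    formal_charge: float  # e
    lattice: TubeLattice

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise BuilderError("diameter must be positive")
        if abs(self.actual_length - self.spec.target_length) > self.spec.axial_period:
            raise BuilderError(
                "actual_length deviates from target by more than one axial period"
            )


def _ring_arcs(n: int, ring_parity: int) -> np.ndarray:
    """Arc positions (units of a_cc) of the 2n atoms in one circumferential ring."""
    k = np.arange(n)
    if ring_parity % 2 == 0:
        arcs = np.concatenate([3.0 * k, 3.0 * k + 1.0])
    else:
        arcs = np.concatenate([3.0 * k + 1.5, 3.0 * k + 2.5])
    return np.sort(arcs)


def build_armchair_swcnt(spec: NanotubeSpec) -> BuiltTube:
    """Build an armchair (n,n) tube of whole translational unit cells.

    The realized length is the whole number of unit cells (4n atoms each,
    two circumferential rings of 2n atoms) closest to ``target_length``;
    ``actual_length`` reports the tip-to-tip coordinate span.  Deterministic:
    no randomness enters the build.
    """
    n = spec.n
    period = spec.axial_period
    n_cells = max(1, round(spec.target_length / period))
    if spec.target_length < period / 2:
        raise BuilderError(
            f"target_length {spec.target_length} nm is shorter than one ring "
            f"spacing ({period / 2:.4f} nm)"
        )
    n_rings = 2 * n_cells
    radius = spec.diameter_closed_form / 2.0
    angle_per_arc = 2.0 * math.pi / (3.0 * n)  # rolls arc length a_cc

    atoms: list[AtomRecord] = []
    z0 = -(n_rings - 1) * (period / 2.0) / 2.0
    for ring in range(n_rings):
        z = z0 + ring * period / 2.0
        for arc in _ring_arcs(n, ring):
            phi = arc * angle_per_arc
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name="C",
                    element="C",
                    residue_name="CNT",
                    residue_id=1,
                    chain_id="X",
                    position=(radius * math.cos(phi), radius * math.sin(phi), z),
                )
            )
    structure = Structure(
        atoms=atoms, groups={"cnt": frozenset(range(len(atoms)))}
    )
    coords = structure.positions
    radial = np.hypot(coords[:, 0], coords[:, 1])
    diameter = 2.0 * float(radial.mean())
    actual_length = float(coords[:, 2].max() - coords[:, 2].min())
    rim = tuple(
        int(i)
        for i in range(len(atoms))
        if i < 2 * n or i >= len(atoms) - 2 * n
    )
    hexagons = find_hexagons(coords, bond_cutoff=1.15 * spec.cc_bond)
    lattice = TubeLattice(
        cnt_indices=tuple(range(len(atoms))),
        hexagons=hexagons,
        rim_indices=rim,
    )
    return BuiltTube(
        structure=structure,
        spec=spec,
        actual_length=actual_length,
        diameter=diameter,
        formal_charge=0.0,
        lattice=lattice,
    )


def find_hexagons(
    coords: np.ndarray, bond_cutoff: float = 0.16, indices: Optional[Sequence[int]] = None
) -> tuple[tuple[int, ...], ...]:
    """Enumerate hexagonal rings (6-cycles of the bond graph) in ``coords``.

    ``indices`` restricts the search to a subset of atoms (returned tuples
    are in the original index space).  Bonds are pairs closer than
    ``bond_cutoff`` nm.
    """
    coords = np.asarray(coords, dtype=float)
    if indices is None:
        idx = np.arange(len(coords))
    else:
        idx = np.asarray(sorted(indices), dtype=int)
    sub = coords[idx]
    tree = cKDTree(sub)
    pairs = tree.query_pairs(bond_cutoff)
    adj: dict[int, list[int]] = {i: [] for i in range(len(sub))}
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)

    hexes: set[tuple[int, ...]] = set()
    for start in range(len(sub)):
        # DFS for 6-cycles anchored at their smallest vertex
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            if len(path) == 6:
                if start in adj[node] and path[1] < path[-1]:
                    hexes.add(tuple(sorted(path)))
                continue
            for nxt in adj[node]:
                if nxt <= start or nxt in path:
                    continue
                stack.append((nxt, path + [nxt]))
    return tuple(
        sorted(tuple(int(idx[i]) for i in h) for h in hexes)
    )


_CARBOXYL_CO = 0.125  # nm
_CARBOXYL_CC = 0.142  # nm
_CARBOXYL_OCO = math.radians(124.0)


def carboxylate_edges(tube: BuiltTube, count: int, seed: int = 0) -> BuiltTube:
    """Attach ``count`` carboxylate groups (C + 2 O, formal charge -1 each)
    to rim carbons, split as evenly as possible between the two rims.

    Deterministic for a given seed: the seed picks the angular offset of the
    evenly spaced attachment sites on each rim.  Returns a new BuiltTube; the
    input is not modified.
    """
    if count < 0:
        raise BuilderError("carboxylate count must be non-negative")
    if count == 0:
        return BuiltTube(
            structure=tube.structure,
            spec=tube.spec,
            actual_length=tube.actual_length,
            diameter=tube.diameter,
            formal_charge=0.0,
            lattice=tube.lattice,
        )
    n = tube.spec.n
    rim_capacity = 4 * n
    if count > rim_capacity:
        raise BuilderError(
            f"carboxylate count {count} exceeds rim capacity {rim_capacity} "
            "(rim capacity exceeded)"
        )
    coords = tube.structure.positions
    z = coords[:, 2]
    rim = np.asarray(tube.lattice.rim_indices, dtype=int)
    bottom = rim[z[rim] < 0]
    top = rim[z[rim] >= 0]
    n_top = count - count // 2
    n_bottom = count // 2

    rng = np.random.default_rng(seed)
    sites: list[int] = []
    for rim_atoms, k in ((top, n_top), (bottom, n_bottom)):
        if k == 0:
            continue
        order = rim_atoms[np.argsort(np.arctan2(coords[rim_atoms, 1], coords[rim_atoms, 0]))]
        start = int(rng.integers(len(order)))
        picks = {(start + round(j * len(order) / k)) % len(order) for j in range(k)}
        while len(picks) < k:  # collisions from rounding
            picks.add(int(rng.integers(len(order))))
        sites.extend(int(order[p]) for p in sorted(picks))

    atoms = list(tube.structure.atoms)
    new_indices: list[int] = []
    axis = np.array([0.0, 0.0, 1.0])
    half = _CARBOXYL_OCO / 2.0
    for g, site in enumerate(sites):
        p = coords[site]
        axial = axis if p[2] >= 0 else -axis
        radial = np.array([p[0], p[1], 0.0])
        radial /= np.linalg.norm(radial)
        c_pos = p + _CARBOXYL_CC * axial
        o1 = c_pos + _CARBOXYL_CO * (math.cos(half) * axial + math.sin(half) * radial)
        o2 = c_pos + _CARBOXYL_CO * (math.cos(half) * axial - math.sin(half) * radial)
        resid = 1000 + g
        for name, element, pos in (("C", "C", c_pos), ("O1", "O", o1), ("O2", "O", o2)):
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=name,
                    element=element,
                    residue_name="CBX",
                    residue_id=resid,
                    chain_id="X",
                    position=tuple(pos),
                )
            )
            new_indices.append(atoms[-1].index)

    groups = dict(tube.structure.groups)
    groups["carboxyl"] = frozenset(new_indices)
    structure = Structure(atoms=atoms, box=tube.structure.box, groups=groups)
    return BuiltTube(
        structure=structure,
        spec=tube.spec,
        actual_length=tube.actual_length,
        diameter=tube.diameter,
        formal_charge=-float(count),
        lattice=tube.lattice,
    )


# (group, element) -> (epsilon kJ/mol, sigma nm, charge e).  The tube carbon
# values are the uncharged LJ parameters used throughout; the protein block
# is a deliberately simple element-keyed table (NOT a full force field), so
# absolute energies are comparable only in trend.
PARAMETER_TABLES: dict[str, dict[tuple[str, str], tuple[float, float, float]]] = {
    "simple_v1": {
        ("cnt", "C"): (0.36, 0.34, 0.0),
        ("carboxyl", "C"): (0.36, 0.34, 0.0),
        ("carboxyl", "O"): (0.65, 0.296, -0.5),
        ("protein", "C"): (0.30, 0.350, 0.0),
        ("protein", "N"): (0.70, 0.325, 0.0),
        ("protein", "O"): (0.80, 0.296, 0.0),
        ("protein", "S"): (1.00, 0.356, 0.0),
        ("protein", "H"): (0.08, 0.120, 0.0),
        ("protein", "P"): (0.85, 0.374, 0.0),
    }
}

# Formal charges layered on top of the element table, keyed by
# (residue_name, atom name).  Histidine is only cationic when explicitly
# renamed HIP by the caller (protonation is input-dependent).
_FORMAL_CHARGES: dict[tuple[str, str], float] = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("HIP", "ND1"): 0.5,
    ("HIP", "NE2"): 0.5,
}


def assign_nonbonded_params(
    structure: Structure, parameter_table: str = "simple_v1"
) -> NonbondedParams:
    """Assign per-atom LJ parameters and charges from a bundled table.

    Atoms in group ``cnt``/``carboxyl`` use the tube entries; all others use
    the protein element entries.  Carboxylate oxygens carry -0.5 e each so a
    3-atom group sums to -1 e.  Unknown (group, element) pairs are an error
    that lists the offending atoms.
    """
    try:
        table = PARAMETER_TABLES[parameter_table]
    except KeyError:
        raise ParameterError(
            f"unknown parameter table {parameter_table!r}; "
            f"available: {sorted(PARAMETER_TABLES)}"
        ) from None
    cnt = structure.groups.get("cnt", frozenset())
    carboxyl = structure.groups.get("carboxyl", frozenset())
    n = structure.n_atoms
    eps = np.empty(n)
    sig = np.empty(n)
    q = np.empty(n)
    missing: list[str] = []
    for atom in structure.atoms:
        if atom.index in cnt:
            group = "cnt"
        elif atom.index in carboxyl:
            group = "carboxyl"
        else:
            group = "protein"
        key = (group, atom.element[0].upper() + atom.element[1:].lower())
        if key not in table:
            missing.append(f"atom {atom.index} {atom.name} ({group}, {atom.element})")
            continue
        e, s, c = table[key]
        eps[atom.index] = e
        sig[atom.index] = s
        if group == "protein":
            c = _FORMAL_CHARGES.get(
                (atom.residue_name.upper(), atom.name.upper()), c
            )
        q[atom.index] = c
    if missing:
        raise ParameterError(
            "no nonbonded parameters for: " + "; ".join(missing[:10])
            + ("; ..." if len(missing) > 10 else "")
        )
    return NonbondedParams(epsilon=eps, sigma=sig, charge=q)


def merge_structures(first: Structure, second: Structure) -> tuple[Structure, int]:
    """Concatenate two structures; returns (merged, index offset of second)."""
    offset = first.n_atoms
    atoms = list(first.atoms)
    for atom in second.atoms:
        atoms.append(
            AtomRecord(
                index=len(atoms),
                name=atom.name,
                element=atom.element,
                residue_name=atom.residue_name,
                residue_id=atom.residue_id,
                chain_id=atom.chain_id,
                position=atom.position,
            )
        )
    groups = {k: frozenset(v) for k, v in first.groups.items()}
    for k, v in second.groups.items():
        shifted = frozenset(i + offset for i in v)
        groups[k] = groups.get(k, frozenset()) | shifted
    return Structure(atoms=atoms, box=first.box, groups=groups), offset


_POSE_MODES = ("sidewall_facing", "end_on", "sidewall_and_edge", "face_3_and_S")
_POSE_STEP = 0.05  # nm, deterministic placement search step
_POSE_TRIALS = 100


def _perpendicular_unit(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    out = np.cross(v, ref)
    return out / np.linalg.norm(out)


def pose_system(
    protein: Structure,
    tube: BuiltTube,
    channel,
    mode: str,
    gap: float,
) -> tuple[Structure, TubeLattice]:
    """Rigidly place ``tube`` against ``protein`` at a channel mouth.

    ``channel`` is a ChannelSpec (see :mod:`cntkit.occlusion`).  The tube
    axis is set perpendicular (sidewall modes) or parallel (``end_on``) to
    the mouth outward vector, then translated outward along it in 0.05 nm
    steps until no inter-body heavy-atom pair is closer than ``gap``.
    Deterministic; returns the merged structure (protein first, group
    ``protein`` registered) and the tube lattice re-based into it.
    """
    from .occlusion import mouth_geometry  # local import avoids a cycle

    if gap <= 0:
        raise BuilderError("gap must be positive")
    if mode not in _POSE_MODES:
        raise BuilderError(f"unknown mode {mode!r}; expected one of {_POSE_MODES}")

    centroid, outward = mouth_geometry(protein.positions, protein, channel)
    tube_coords = tube.structure.positions
    tube_center = tube_coords.mean(axis=0)
    local = tube_coords - tube_center

    if mode == "end_on":
        new_axis = outward
    else:
        new_axis = _perpendicular_unit(outward)
    # rotate the builder z axis onto new_axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, new_axis)
    s = np.linalg.norm(v)
    c = float(np.dot(z, new_axis))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    local = local @ rot.T

    axial_shift = np.zeros(3)
    if mode == "sidewall_and_edge":
        axial_shift = new_axis * (tube.actual_length / 2.0)
    rim_lead = tube.actual_length / 2.0 if mode == "end_on" else 0.0

    protein_coords = protein.positions
    heavy_p = protein.heavy_mask
    heavy_t = tube.structure.heavy_mask
    p_heavy = protein_coords[heavy_p]
    tree = cKDTree(p_heavy)

    placed = None
    for trial in range(_POSE_TRIALS):
        d = trial * _POSE_STEP
        center = centroid + outward * (d + rim_lead) + axial_shift
        candidate = local + center
        dmin, _ = tree.query(candidate[heavy_t], k=1)
        if float(dmin.min()) >= gap:
            placed = candidate
            break
    if placed is None:
        raise BuilderError(
            f"steric clash unresolvable within {_POSE_TRIALS} trial placements "
            f"(gap {gap} nm)"
        )

    posed_tube = tube.structure.with_positions(placed)
    protein_grouped = protein.with_groups(protein=range(protein.n_atoms))
    merged, offset = merge_structures(protein_grouped, posed_tube)
    return merged, tube.lattice.shifted(offset)


def write_parameter_sidecar(params: NonbondedParams, path) -> None:
    """Plain-text sidecar: index, epsilon (kJ/mol), sigma (nm), charge (e)."""
    lines = ["# index epsilon_kJmol sigma_nm charge_e\n"]
    for i in range(params.n_atoms):
        lines.append(
            f"{i} {params.epsilon[i]:.6g} {params.sigma[i]:.6g} {params.charge[i]:.6g}\n"
        )
    Path(path).write_text("".join(lines))


def write_build_report(tube: BuiltTube, path) -> None:
    report = {
        "spec": {
            "n": tube.spec.n,
            "target_length_nm": tube.spec.target_length,
            "cc_bond_nm": tube.spec.cc_bond,
            "carboxyl_count": tube.spec.carboxyl_count,
            "seed": tube.spec.seed,
        },
        "actual_length_nm": tube.actual_length,
        "diameter_nm": tube.diameter,
        "formal_charge_e": tube.formal_charge,
        "n_atoms": tube.structure.n_atoms,
        "n_carbon": len(tube.lattice.cnt_indices),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
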