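"""Per-frame interaction fingerprints between a protein and a nanotube.

Detectors: heavy-atom contacts, per-residue contact-ratio tables,
hydrogen bonds, salt bridges, and pi-pi stacking classified as parallel
(face-to-face) or T-shape (edge-to-face) against the local tube surface.

All geometric thresholds are config-exposed; the defaults are common
trajectory-analysis values.  The tube is treated locally: the reference
ring is the nearest lattice hexagon and the surface normal is the radial
unit vector at that hexagon's centroid, because the tube is curved and a
single plane would be wrong.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .builder import TubeLattice
from .model import Selection, Structure, Trajectory

__all__ = [
    "ContactCriteria",
    "HBondCriteria",
    "SaltBridgeCriteria",
    "StackingCriteria",
    "ContactRatioTable",
    "StackEvent",
    "StackingRatio",
    "FingerprintError",
    "RING_ATOMS",
    "contact_count",
    "contact_ratio_table",
    "detect_hbonds",
    "detect_salt_bridges",
    "detect_pi_stacking",
    "stacking_formation_ratio",
    "aromatic_rings",
    "residue_selections",
]

PERSISTENCE_THRESHOLD = 0.5  # fraction of frames: "over 50% of the simulation time"


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class ContactCriteria:
    cutoff: float = 0.5  # nm
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise FingerprintError("contact cutoff must be positive")


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = 0.35  # nm, donor-acceptor
    dha_angle_min: float = 150.0  # degrees at the hydrogen

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise FingerprintError("donor-acceptor cutoff must be positive")
        if not (90.0 < self.dha_angle_min <= 180.0):
            raise FingerprintError("dha_angle_min must lie in (90, 180]")


@dataclass(frozen=True)
class SaltBridgeCriteria:
    no_cutoff: float = 0.4  # nm, cationic N to anionic O

    def __post_init__(self) -> None:
        if self.no_cutoff <= 0:
            raise FingerprintError("salt-bridge cutoff must be positive")


@dataclass(frozen=True)
class StackingCriteria:
    parallel_centroid_max: float = 0.45  # nm
    parallel_angle_max: float = 30.0  # degrees
    parallel_offset_max: float = 0.20  # nm
    tshape_centroid_max: float = 0.55  # nm
    tshape_angle_range: tuple[float, float] = (60.0, 90.0)

    def __post_init__(self) -> None:
        for d in (
            self.parallel_centroid_max,
            self.parallel_offset_max,
            self.tshape_centroid_max,
        ):
            if d <= 0:
                raise FingerprintError("stacking distances must be positive")
        lo, hi = self.tshape_angle_range
        if not (0.0 <= self.parallel_angle_max <= 90.0 and 0.0 <= lo <= hi <= 90.0):
            raise FingerprintError("stacking angle ranges must lie within [0, 90]")


ResidueKey = tuple[str, int, str]  # (chain_id, residue_id, residue_name)


@dataclass(frozen=True)
class StackEvent:
    frame: int
    residue: ResidueKey
    ring_centroid_distance: float  # nm
    interplanar_angle: float  # degrees, acute, vs the local surface normal
    lateral_offset: float  # nm
    cls: str  # "parallel" | "tshape"


@dataclass
class StackingRatio:
    residue: ResidueKey
    ratio: float
    parallel_fraction: float
    tshape_fraction: float
    n_frames: int

    @property
    def persistent(self) -> bool:
        return self.ratio > PERSISTENCE_THRESHOLD


@dataclass
class ContactRatioRow:
    residue: ResidueKey
    fraction: float
    n_frames: int

    @property
    def persistent(self) -> bool:
        return self.fraction > PERSISTENCE_THRESHOLD


@dataclass
class ContactRatioTable:
    rows: list[ContactRatioRow]
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r.residue[0] for r in self.rows],
                "residue_id": [r.residue[1] for r in self.rows],
                "residue_name": [r.residue[2] for r in self.rows],
                "fraction": [r.fraction for r in self.rows],
                "n_frames": [r.n_frames for r in self.rows],
                "persistent": [r.persistent for r in self.rows],
            }
        )


def _heavy_filter(
    structure: Structure, indices: np.ndarray, heavy_only: bool
) -> np.ndarray:
    if not heavy_only:
        return indices
    mask = np.array([structure.atoms[i].is_heavy for i in indices], dtype=bool)
    return indices[mask]


def contact_count(
    structure: Structure,
    frame: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
    criteria: ContactCriteria = ContactCriteria(),
) -> int:
    """Number of cross pairs within the cutoff; symmetric in A/B."""
    if not sel_a or not sel_b:
        raise FingerprintError("contact selections must be non-empty")
    if sel_a.resolved & sel_b.resolved:
        raise FingerprintError("contact selections must be disjoint")
    frame = np.asarray(frame, dtype=float)
    ia = _heavy_filter(structure, sel_a.indices(), criteria.heavy_only)
    ib = _heavy_filter(structure, sel_b.indices(), criteria.heavy_only)
    if len(ia) == 0 or len(ib) == 0:
        return 0
    d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=2)
    return int(np.count_nonzero(d <= criteria.cutoff))


def residue_selections(
    structure: Structure, residues: Sequence[ResidueKey]
) -> dict[ResidueKey, Selection]:
    """One Selection per residue key, resolved by (chain, residue_id)."""
    out: dict[ResidueKey, Selection] = {}
    for key in residues:
        chain, resid, resname = key
        idx = structure.atoms_of_residue(chain, resid)
        out[key] = Selection(
            expression=f"chain == {chain} and residue_id == {resid}",
            resolved=frozenset(idx),
        )
    return out


def contact_ratio_table(
    trajectory: Trajectory,
    probe_residues: Mapping[ResidueKey, Selection],
    partner: Selection,
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactRatioTable:
    """Fraction of frames each probe residue has >=1 qualifying contact with
    the partner selection; fractions above 0.5 are flagged persistent."""
    if trajectory.n_frames < 1:
        raise FingerprintError("empty trajectory")
    if not partner:
        raise FingerprintError("empty partner selection")
    structure = trajectory.topology
    rows = []
    for key, sel in probe_residues.items():
        if not sel:
            rows.append(ContactRatioRow(residue=key, fraction=0.0, n_frames=trajectory.n_frames))
            continue
        hits = 0
        for k in range(trajectory.n_frames):
            if contact_count(structure, trajectory.frames[k], sel, partner, criteria) > 0:
                hits += 1
        rows.append(
            ContactRatioRow(
                residue=key,
                fraction=hits / trajectory.n_frames,
                n_frames=trajectory.n_frames,
            )
        )
    return ContactRatioTable(rows=rows, n_frames=trajectory.n_frames)


def _attached_hydrogens(
    structure: Structure,
    frame: np.ndarray,
    donor: int,
    hydrogen_map: Optional[Mapping[int, Sequence[int]]],
) -> list[int]:
    if hydrogen_map is not None and donor in hydrogen_map:
        return list(hydrogen_map[donor])
    d_atom = structure.atoms[donor]
    hs = []
    for i in structure.atoms_of_residue(d_atom.chain_id, d_atom.residue_id):
        a = structure.atoms[i]
        if a.element.upper() != "H":
            continue
        if np.linalg.norm(frame[i] - frame[donor]) <= 0.125:
            hs.append(i)
    return hs


def detect_hbonds(
    structure: Structure,
    frame: np.ndarray,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogen_map: Optional[Mapping[int, Sequence[int]]] = None,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the geometric
    criteria: D-A distance <= cutoff and D-H...A angle at H >= minimum.

    Hydrogens are resolved from ``hydrogen_map`` when given, else by
    proximity (<=0.125 nm) within the donor's residue.  A donor with no
    resolvable hydrogen is an error suggesting the explicit map.
    """
    frame = np.asarray(frame, dtype=float)
    triples: list[tuple[int, int, int]] = []
    acc = acceptors.indices()
    if len(acc) == 0:
        return []
    for d in sorted(donors.resolved):
        hs = _attached_hydrogens(structure, frame, d, hydrogen_map)
        if not hs:
            raise FingerprintError(
                f"donor atom {d} ({structure.atoms[d].name}) has no resolvable "
                "attached hydrogen; pass an explicit hydrogen_map"
            )
        da = np.linalg.norm(frame[acc] - frame[d], axis=1)
        for a in acc[da <= criteria.da_cutoff]:
            if int(a) == d:
                continue
            for h in hs:
                v1 = frame[d] - frame[h]
                v2 = frame[a] - frame[h]
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                cos_angle = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
                if np.degrees(np.arccos(cos_angle)) >= criteria.dha_angle_min:
                    triples.append((d, h, int(a)))
                    break  # one H per (donor, acceptor): no duplicates
    return triples


def detect_salt_bridges(
    structure: Structure,
    frame: np.ndarray,
    cations: Selection,
    anions: Selection,
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
    charges: Optional[np.ndarray] = None,
) -> list[tuple[ResidueKey, ResidueKey, float]]:
    """Cationic-N / anionic-O pairs within the cutoff, one entry per
    (cation residue, anion residue) pair at the minimum distance.

    ``charges`` must carry the formal-charge annotations (from
    assign_nonbonded_params or equivalent); only atoms with charge > 0
    (cations) / < 0 (anions) participate.
    """
    if charges is None:
        raise FingerprintError(
            "salt-bridge detection requires formal-charge annotations "
            "(charges array)"
        )
    charges = np.asarray(charges, dtype=float)
    frame = np.asarray(frame, dtype=float)
    cat = np.array([i for i in cations.indices() if charges[i] > 0], dtype=int)
    ani = np.array([i for i in anions.indices() if charges[i] < 0], dtype=int)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for c in cat:
        c_atom = structure.atoms[c]
        ckey = (c_atom.chain_id, c_atom.residue_id, c_atom.residue_name)
        d = np.linalg.norm(frame[ani] - frame[c], axis=1) if len(ani) else np.array([])
        for j, a in enumerate(ani):
            if d[j] > criteria.no_cutoff:
                continue
            a_atom = structure.atoms[a]
            akey = (a_atom.chain_id, a_atom.residue_id, a_atom.residue_name)
            pair = (ckey, akey)
            if pair not in best or d[j] < best[pair]:
                best[pair] = float(d[j])
    return sorted(
        [(c, a, dist) for (c, a), dist in best.items()],
        key=lambda t: (t[0], t[1]),
    )


RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "HIP": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class Ring:
    residue: ResidueKey
    atom_indices: tuple[int, ...]


def aromatic_rings(structure: Structure) -> list[Ring]:
    """Ring atom sets for every aromatic residue with a complete ring."""
    rings: list[Ring] = []
    for chain, resid, resname in structure.residues():
        wanted = RING_ATOMS.get(resname.upper())
        if wanted is None:
            continue
        idx_by_name = {
            structure.atoms[i].name.upper(): i
            for i in structure.atoms_of_residue(chain, resid)
        }
        if all(name in idx_by_name for name in wanted):
            rings.append(
                Ring(
                    residue=(chain, resid, resname),
                    atom_indices=tuple(idx_by_name[name] for name in wanted),
                )
            )
    return rings


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring via SVD plane fit."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise FingerprintError("degenerate (collinear) ring atoms")
    return centroid, vt[2]


def _tube_axis(frame: np.ndarray, cnt_indices: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    pts = frame[np.asarray(cnt_indices, dtype=int)]
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    return center, vt[0]


def detect_pi_stacking(
    structure: Structure,
    frame: np.ndarray,
    rings: Sequence[Ring],
    tube: TubeLattice,
    criteria: StackingCriteria = StackingCriteria(),
    frame_index: int = 0,
) -> list[StackEvent]:
    """Classify each aromatic ring against the local tube surface.

    For every ring the nearest tube lattice hexagon centroid and the radial
    surface normal at that hexagon are computed.  A ring is
    *parallel* when centroid distance, interplanar angle and lateral offset
    are all within the parallel gates, *tshape* when centroid distance and
    angle fall in the T-shape gates.  At most one event per residue per
    frame; parallel wins ties.
    """
    lattice = tube.lattice if hasattr(tube, "lattice") else tube
    frame = np.asarray(frame, dtype=float)
    if not lattice.hexagons:
        raise FingerprintError("tube lattice has no hexagons")
    hex_centroids = np.array(
        [frame[np.asarray(h, dtype=int)].mean(axis=0) for h in lattice.hexagons]
    )
    axis_point, axis_dir = _tube_axis(frame, lattice.cnt_indices)
    cnt_idx = np.asarray(lattice.cnt_indices, dtype=int)
    cnt_pts = frame[cnt_idx]

    events: list[StackEvent] = []
    for ring in rings:
        if len(ring.atom_indices) < 5:
            raise FingerprintError(
                f"ring of residue {ring.residue} has fewer than 5 atoms"
            )
        centroid, normal = _ring_plane(frame[list(ring.atom_indices)])

        d_hex = np.linalg.norm(hex_centroids - centroid, axis=1)
        nearest_hex = int(np.argmin(d_hex))
        centroid_distance = float(d_hex[nearest_hex])

        # local surface normal: radial direction at the stacked hexagon
        # (the nearest-atom radial wobbles by half a hexagon's angular width)
        radial = hex_centroids[nearest_hex] - axis_point
        radial = radial - np.dot(radial, axis_dir) * axis_dir
        norm = np.linalg.norm(radial)
        if norm < 1e-9:
            continue  # degenerate: hexagon centroid on the tube axis
        surface_normal = radial / norm

        cosang = abs(float(np.clip(np.dot(normal, surface_normal), -1.0, 1.0)))
        angle = float(np.degrees(np.arccos(cosang)))

        offset_vec = centroid - hex_centroids[nearest_hex]
        lateral = offset_vec - np.dot(offset_vec, surface_normal) * surface_normal
        lateral_offset = float(np.linalg.norm(lateral))

        is_parallel = (
            centroid_distance <= criteria.parallel_centroid_max
            and angle <= criteria.parallel_angle_max
            and lateral_offset <= criteria.parallel_offset_max
        )
        lo, hi = criteria.tshape_angle_range
        is_tshape = centroid_distance <= criteria.tshape_centroid_max and lo <= angle <= hi
        if is_parallel:
            cls = "parallel"
        elif is_tshape:
            cls = "tshape"
        else:
            continue
        events.append(
            StackEvent(
                frame=frame_index,
                residue=ring.residue,
                ring_centroid_distance=centroid_distance,
                interplanar_angle=angle,
                lateral_offset=lateral_offset,
                cls=cls,
            )
        )
    return events


def stacking_formation_ratio(
    trajectory: Trajectory,
    residue: ResidueKey,
    tube: TubeLattice,
    criteria: StackingCriteria = StackingCriteria(),
) -> StackingRatio:
    """Fraction of frames with any stacking event for one aromatic residue,
    with the parallel / T-shape breakdown."""
    chain, resid, resname = residue
    if resname.upper() not in RING_ATOMS:
        raise FingerprintError(f"residue {residue} is not aromatic")
    rings = [r for r in aromatic_rings(trajectory.topology) if r.residue == residue]
    if not rings:
        raise FingerprintError(f"residue {residue} has no complete aromatic ring")
    n_par = n_t = 0
    for k in range(trajectory.n_frames):
        events = detect_pi_stacking(
            trajectory.topology, trajectory.frames[k], rings, tube, criteria, frame_index=k
        )
        if any(e.cls == "parallel" for e in events):
            n_par += 1
        elif any(e.cls == "tshape" for e in events):
            n_t += 1
    n = trajectory.n_frames
    return StackingRatio(
        residue=residue,
        ratio=(n_par + n_t) / n,
        parallel_fraction=n_par / n,
        tshape_fraction=n_t / n,
        n_frames=n,
    )
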