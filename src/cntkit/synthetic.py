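"""Seeded toy trajectories with injected, exactly-known interaction events.

A small carboxylated tube sits fixed at the origin; a pseudo-residue host
scaffold provides named aromatic / cationic / donor / channel-lining sites.
Events are scripted kinematically: during an event's frame range the target
residue is rigidly posed so the corresponding detector's criteria hold with
>=20% margin on every threshold, and outside the range the residue sits far
away, violating them with at least the same margin.  Gaussian coordinate
jitter (one seed for all randomness) is applied last, so the ground truth is
exact by construction at zero jitter and degrades gracefully with sigma.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .builder import (
    BuiltTube,
    NanotubeSpec,
    TubeLattice,
    assign_nonbonded_params,
    build_armchair_swcnt,
    carboxylate_edges,
    merge_structures,
)
from .fingerprints import (
    ContactCriteria,
    HBondCriteria,
    SaltBridgeCriteria,
    StackingCriteria,
    StackingRatio,
    aromatic_rings,
    contact_ratio_table,
    detect_hbonds,
    detect_pi_stacking,
    detect_salt_bridges,
    residue_selections,
)
from .model import AtomRecord, Selection, Structure, Trajectory
from .occlusion import (
    BlockingProfile,
    ChannelSpec,
    blocking_onset,
)
from .selection import resolve_selection

__all__ = [
    "Event",
    "ScenarioSpec",
    "GroundTruth",
    "ScenarioError",
    "DetectorOutputs",
    "RecoveryReport",
    "generate_scenario",
    "default_scenario",
    "toy_channel",
    "run_detectors",
    "recovery_report",
    "write_scenario",
    "build_hydrogen_map",
]

EVENT_KINDS = ("stack_parallel", "stack_tshape", "salt_bridge", "hbond", "channel_block")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """A scripted interaction over the half-open frame range [start, end)."""

    kind: str
    target: str  # residue label like "PHE2", or channel id for channel_block
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScenarioError(f"unknown event kind {self.kind!r}")
        if not (0 <= self.start_frame < self.end_frame):
            raise ScenarioError(
                f"event frames must satisfy 0 <= start < end, got "
                f"[{self.start_frame}, {self.end_frame})"
            )

    def active(self, frame: int) -> bool:
        return self.start_frame <= frame < self.end_frame


@dataclass(frozen=True)
class ScenarioSpec:
    n_frames: int = 100
    frame_spacing: float = 1000.0  # ps (1 ns per frame)
    tube: NanotubeSpec = field(
        default_factory=lambda: NanotubeSpec(n=5, target_length=1.0, carboxyl_count=4)
    )
    events: tuple[Event, ...] = ()
    jitter_sigma: float = 0.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ScenarioError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ScenarioError("jitter_sigma must be >= 0")
        for ev in self.events:
            if ev.end_frame > self.n_frames:
                raise ScenarioError(
                    f"event {ev.kind} on {ev.target}: end_frame {ev.end_frame} "
                    f"exceeds n_frames {self.n_frames}"
                )
        by_target: dict[str, list[Event]] = {}
        for ev in self.events:
            by_target.setdefault(ev.target, []).append(ev)
        for target, evs in by_target.items():
            evs = sorted(evs, key=lambda e: e.start_frame)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.start_frame < prev.end_frame:
                    raise ScenarioError(
                        f"events geometrically incompatible: {target} is scripted "
                        f"into two poses simultaneously in frames "
                        f"[{nxt.start_frame}, {prev.end_frame})"
                    )


# ---------------------------------------------------------------------------
# host scaffold

# label -> (resid, resname, atom names); chain is always "A"
_HOST_RESIDUES: tuple[tuple[int, str, tuple[str, ...]], ...] = (
    (2, "PHE", ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    (3, "LYS", ("CE", "NZ")),
    (4, "GLN", ("CD", "OE1", "NE2", "HE21")),
    (5, "GLY", ("N", "H", "CA", "C", "O")),
    (6, "SER", ("CB", "OG", "HG")),
    (10, "ALA", ("CA",)),
    (11, "ALA", ("CA",)),
    (12, "ALA", ("CA",)),
    (20, "ALA", ("CA",)),
    (21, "ALA", ("CA",)),
    (22, "ALA", ("CA",)),
    (23, "ALA", ("CA",)),
)

_DONOR_H = {"GLN": ("NE2", "HE21"), "GLY": ("N", "H"), "SER": ("OG", "HG")}
_RING_RADIUS = 0.139  # nm, ideal aromatic C-C ring


def _host_label(resid: int, resname: str) -> str:
    return f"{resname}{resid}"


def _far_anchor(slot: int) -> np.ndarray:
    """Resting position for residue slot: a ring of radius 3 nm around the tube."""
    angle = 2.0 * math.pi * slot / len(_HOST_RESIDUES)
    return np.array([3.0 * math.cos(angle), 3.0 * math.sin(angle), 0.0])


def _residue_base_coords(resname: str, names: Sequence[str], anchor: np.ndarray) -> list[np.ndarray]:
    """Compact default layout around the anchor (0.1-0.15 nm spacing)."""
    u = anchor / np.linalg.norm(anchor)
    perp = np.cross(np.array([0.0, 0.0, 1.0]), u)
    coords = []
    if resname == "PHE":
        center = anchor
        e1, e2 = np.array([0.0, 0.0, 1.0]), perp
        coords.append(center + 0.25 * u)  # CB
        for k in range(6):
            theta = math.radians(60.0 * k)
            coords.append(center + _RING_RADIUS * (math.cos(theta) * e1 + math.sin(theta) * e2))
    else:
        for j, _ in enumerate(names):
            coords.append(anchor + 0.13 * j * u)
    return coords


def _make_host(tube: BuiltTube) -> Structure:
    atoms: list[AtomRecord] = []
    for slot, (resid, resname, names) in enumerate(_HOST_RESIDUES):
        anchor = _far_anchor(slot)
        if 10 <= resid <= 12:
            # lining Calphas rest above the open tube end
            anchor = np.array([0.0, 0.3 * (resid - 11), 3.0])
        if resid >= 20:
            anchor = _far_anchor(slot) * 1.3 + np.array([0.0, 0.0, -1.0])
        coords = _residue_base_coords(resname, names, anchor)
        for name, pos in zip(names, coords):
            element = "H" if name.startswith("H") else name[0]
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_id=resid,
                    chain_id="A",
                    position=tuple(pos),
                )
            )
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# event poses

def _mid_hexagon(tube: BuiltTube) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and outward radial normal of the hexagon nearest the tube middle."""
    coords = tube.structure.positions
    cents = np.array([coords[list(h)].mean(axis=0) for h in tube.lattice.hexagons])
    mid = int(np.argmin(np.abs(cents[:, 2])))
    c = cents[mid]
    radial = np.array([c[0], c[1], 0.0])
    return c, radial / np.linalg.norm(radial)


def _top_carboxyl_oxygen(tube: BuiltTube) -> np.ndarray:
    carboxyl = tube.structure.groups.get("carboxyl")
    if not carboxyl:
        raise ScenarioError("scenario tube has no carboxyl groups")
    coords = tube.structure.positions
    oxy = [i for i in sorted(carboxyl) if tube.structure.atoms[i].element == "O"]
    return coords[max(oxy, key=lambda i: coords[i][2])]


def _pose_stack(tube: BuiltTube, names: Sequence[str], parallel: bool) -> np.ndarray:
    hc, nrm = _mid_hexagon(tube)
    z = np.array([0.0, 0.0, 1.0])
    side = np.cross(nrm, z)
    if parallel:
        center = hc + 0.35 * nrm  # 22% inside the 0.45 nm gate
        e1, e2 = z, side
    else:
        center = hc + 0.42 * nrm  # 24% inside the 0.55 nm T-shape gate
        e1, e2 = nrm, z  # ring plane contains the normal: 90 deg
    out = [center + 0.25 * nrm]  # CB kept outward
    for k in range(6):
        theta = math.radians(60.0 * k)
        out.append(center + _RING_RADIUS * (math.cos(theta) * e1 + math.sin(theta) * e2))
    assert len(out) == len(names)
    return np.array(out)


def _pose_salt_bridge(tube: BuiltTube, names: Sequence[str]) -> np.ndarray:
    o = _top_carboxyl_oxygen(tube)
    u = o / np.linalg.norm(o)
    nz = o + 0.30 * u  # 25% inside the 0.4 nm gate
    ce = nz + 0.152 * u
    coords = {"NZ": nz, "CE": ce}
    return np.array([coords[n] for n in names])


def _pose_hbond(tube: BuiltTube, resname: str, names: Sequence[str]) -> np.ndarray:
    o = _top_carboxyl_oxygen(tube)
    u = o / np.linalg.norm(o)
    donor_name, h_name = _DONOR_H[resname]
    donor = o + 0.27 * u  # 23% inside the 0.35 nm gate, angle exactly 180
    hydrogen = o + 0.17 * u
    out = []
    j = 0
    for name in names:
        if name == donor_name:
            out.append(donor)
        elif name == h_name:
            out.append(hydrogen)
        else:
            j += 1
            out.append(donor + 0.14 * j * u)
    return np.array(out)


def _pose_block(tube: BuiltTube, resid: int) -> np.ndarray:
    radius = tube.diameter / 2.0
    center = np.array([radius + 0.45, 0.0, 0.0])  # 36% inside the 0.7 nm gate
    k = resid - 10
    theta = math.radians(120.0 * k)
    return np.array([center + 0.3 * (math.cos(theta) * np.array([0.0, 1.0, 0.0])
                                     + math.sin(theta) * np.array([0.0, 0.0, 1.0]))])


# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact event bookkeeping implied by a ScenarioSpec."""

    n_frames: int
    frame_spacing: float  # ps
    events: tuple[Event, ...]
    blocking_onset_frame: dict[str, Optional[int]]
    stacking_ratio: dict[str, float]
    stacking_parallel: dict[str, float]
    stacking_tshape: dict[str, float]
    salt_bridge_frames: dict[str, frozenset[int]]
    hbond_frames: dict[str, frozenset[int]]

    def to_json(self) -> str:
        payload = {
            "n_frames": self.n_frames,
            "frame_spacing_ps": self.frame_spacing,
            "events": [
                {"kind": e.kind, "target": e.target,
                 "start_frame": e.start_frame, "end_frame": e.end_frame}
                for e in self.events
            ],
            "blocking_onset_frame": self.blocking_onset_frame,
            "stacking_ratio": self.stacking_ratio,
            "stacking_parallel": self.stacking_parallel,
            "stacking_tshape": self.stacking_tshape,
            "salt_bridge_frames": {k: sorted(v) for k, v in self.salt_bridge_frames.items()},
            "hbond_frames": {k: sorted(v) for k, v in self.hbond_frames.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def toy_channel(block_distance: float = 0.7) -> ChannelSpec:
    return ChannelSpec(
        id="2e",
        lining_residues="residue_id == 10 or residue_id == 11 or residue_id == 12",
        block_distance=block_distance,
    )


def _derive_truth(spec: ScenarioSpec) -> GroundTruth:
    block_flags: dict[str, np.ndarray] = {}
    stack_any: dict[str, set[int]] = {}
    stack_par: dict[str, set[int]] = {}
    stack_t: dict[str, set[int]] = {}
    salt: dict[str, set[int]] = {}
    hbond: dict[str, set[int]] = {}
    for ev in spec.events:
        frames = set(range(ev.start_frame, ev.end_frame))
        if ev.kind == "channel_block":
            flags = block_flags.setdefault(ev.target, np.zeros(spec.n_frames, dtype=bool))
            flags[ev.start_frame:ev.end_frame] = True
        elif ev.kind == "stack_parallel":
            stack_any.setdefault(ev.target, set()).update(frames)
            stack_par.setdefault(ev.target, set()).update(frames)
        elif ev.kind == "stack_tshape":
            stack_any.setdefault(ev.target, set()).update(frames)
            stack_t.setdefault(ev.target, set()).update(frames)
        elif ev.kind == "salt_bridge":
            salt.setdefault(ev.target, set()).update(frames)
        elif ev.kind == "hbond":
            hbond.setdefault(ev.target, set()).update(frames)
    onsets: dict[str, Optional[int]] = {}
    for channel_id, flags in block_flags.items():
        onset = None
        for k in range(spec.n_frames):
            if flags[k:].all():
                onset = k
                break
        onsets[channel_id] = onset
    n = spec.n_frames
    return GroundTruth(
        n_frames=n,
        frame_spacing=spec.frame_spacing,
        events=spec.events,
        blocking_onset_frame=onsets,
        stacking_ratio={k: len(v) / n for k, v in stack_any.items()},
        stacking_parallel={k: len(v) / n for k, v in stack_par.items()},
        stacking_tshape={k: len(v) / n for k, v in stack_t.items()},
        salt_bridge_frames={k: frozenset(v) for k, v in salt.items()},
        hbond_frames={k: frozenset(v) for k, v in hbond.items()},
    )


def generate_scenario(spec: ScenarioSpec) -> tuple[Trajectory, GroundTruth, TubeLattice]:
    """Build the scripted trajectory and its exact ground truth.

    Identical seeds give bit-identical trajectories.  Returns the tube
    lattice (re-based into the merged topology) alongside, since stacking
    detection needs the hexagon index sets.
    """
    tube = build_armchair_swcnt(spec.tube)
    if spec.tube.carboxyl_count:
        tube = carboxylate_edges(tube, spec.tube.carboxyl_count, spec.tube.seed)
    host = _make_host(tube)
    merged, offset = merge_structures(tube.structure, host)
    merged = merged.with_groups(protein=range(offset, merged.n_atoms))
    lattice = tube.lattice  # tube comes first: indices unchanged

    label_to_indices: dict[str, list[int]] = {}
    label_to_resinfo: dict[str, tuple[int, str, tuple[str, ...]]] = {}
    for resid, resname, names in _HOST_RESIDUES:
        label = _host_label(resid, resname)
        idx = [
            a.index
            for a in merged.atoms
            if a.chain_id == "A" and a.residue_id == resid
        ]
        label_to_indices[label] = idx
        label_to_resinfo[label] = (resid, resname, names)

    valid_targets = set(label_to_indices) | {"2e"}
    for ev in spec.events:
        if ev.target not in valid_targets:
            raise ScenarioError(
                f"event target {ev.target!r} unknown; valid: {sorted(valid_targets)}"
            )

    # pre-compute the event poses (they are frame-independent)
    poses: dict[tuple[str, str], np.ndarray] = {}
    for ev in spec.events:
        key = (ev.kind, ev.target)
        if key in poses:
            continue
        if ev.kind == "channel_block":
            continue
        resid, resname, names = label_to_resinfo[ev.target]
        if ev.kind in ("stack_parallel", "stack_tshape"):
            if resname not in ("PHE", "TYR", "TRP", "HIS"):
                raise ScenarioError(f"{ev.kind} target {ev.target} is not aromatic")
            poses[key] = _pose_stack(tube, names, parallel=ev.kind == "stack_parallel")
        elif ev.kind == "salt_bridge":
            if resname != "LYS":
                raise ScenarioError(f"salt_bridge target {ev.target} is not cationic")
            poses[key] = _pose_salt_bridge(tube, names)
        elif ev.kind == "hbond":
            if resname not in _DONOR_H:
                raise ScenarioError(f"hbond target {ev.target} has no donor")
            poses[key] = _pose_hbond(tube, resname, names)

    block_pose: dict[str, dict[int, np.ndarray]] = {}
    for ev in spec.events:
        if ev.kind == "channel_block":
            block_pose[ev.target] = {
                resid: _pose_block(tube, resid) for resid in (10, 11, 12)
            }

    base = merged.positions
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, merged.n_atoms, 3))
    for k in range(spec.n_frames):
        coords = base.copy()
        for ev in spec.events:
            if not ev.active(k):
                continue
            if ev.kind == "channel_block":
                for resid, pose in block_pose[ev.target].items():
                    label = _host_label(resid, "ALA")
                    coords[label_to_indices[label]] = pose
            else:
                coords[label_to_indices[ev.target]] = poses[(ev.kind, ev.target)]
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma, coords.shape)
        frames[k] = coords

    times = np.arange(spec.n_frames) * spec.frame_spacing
    trajectory = Trajectory(topology=merged, times=times, frames=frames)
    return trajectory, _derive_truth(spec), lattice


def default_scenario(
    seed: int = 0, n_frames: int = 120, jitter_sigma: float = 0.0
) -> ScenarioSpec:
    """The standard validation recipe: one of everything, blocking from
    one third of the run onward."""
    if n_frames < 12:
        raise ScenarioError("default_scenario needs n_frames >= 12")
    events = (
        Event("stack_parallel", "PHE2", 0, int(0.5 * n_frames)),
        Event("stack_tshape", "PHE2", int(0.6 * n_frames), int(0.75 * n_frames)),
        Event("salt_bridge", "LYS3", int(n_frames / 6), int(2 * n_frames / 3)),
        Event("hbond", "GLN4", int(n_frames / 12), int(0.45 * n_frames)),
        Event("hbond", "GLY5", int(0.4 * n_frames), int(0.8 * n_frames)),
        Event("channel_block", "2e", n_frames // 3, n_frames),
    )
    return ScenarioSpec(
        n_frames=n_frames, events=events, jitter_sigma=jitter_sigma, seed=seed
    )


# ---------------------------------------------------------------------------
# detection + recovery

def build_hydrogen_map(structure: Structure, donors: Sequence[int]) -> dict[int, list[int]]:
    """Attach hydrogens to N/O donors by the usual naming convention
    (H -> N; HG -> OG; HE21 -> NE2; ...)."""
    out: dict[int, list[int]] = {}
    for d in donors:
        atom = structure.atoms[d]
        suffix = atom.name.upper()[1:]
        hs = []
        for i in structure.atoms_of_residue(atom.chain_id, atom.residue_id):
            h = structure.atoms[i]
            if h.element.upper() != "H":
                continue
            h_suffix = h.name.upper()[1:]
            if (suffix == "" and h.name.upper() == "H") or (
                suffix and h_suffix.startswith(suffix)
            ):
                hs.append(i)
        if hs:
            out[d] = hs
    return out


@dataclass
class DetectorOutputs:
    blocking: dict[str, BlockingProfile]
    stacking: dict[str, StackingRatio]
    salt_bridge_frames: dict[str, frozenset[int]]
    hbond_frames: dict[str, frozenset[int]]
    contact_fractions: dict[str, float]


def run_detectors(
    trajectory: Trajectory,
    lattice: TubeLattice,
    channels: Sequence[ChannelSpec] = (),
    contact: ContactCriteria = ContactCriteria(),
    hbond: HBondCriteria = HBondCriteria(),
    salt_bridge: SaltBridgeCriteria = SaltBridgeCriteria(),
    stacking: StackingCriteria = StackingCriteria(),
    persistence: float = 1.0,
) -> DetectorOutputs:
    """Run every fingerprint detector over a scenario trajectory."""
    structure = trajectory.topology
    params = assign_nonbonded_params(structure)
    tube_sel = resolve_selection(structure, "group == cnt or group == carboxyl")
    carboxyl_sel = resolve_selection(structure, "group == carboxyl")

    blocking = {
        ch.id: blocking_onset(trajectory, ch, tube_sel, persistence, run_id=ch.id)
        for ch in channels
    }

    stacking_out: dict[str, StackingRatio] = {}
    for ring in aromatic_rings(structure):
        chain, resid, resname = ring.residue
        from .fingerprints import stacking_formation_ratio

        stacking_out[f"{resname}{resid}"] = stacking_formation_ratio(
            trajectory, ring.residue, lattice, stacking
        )

    cation_idx = [i for i in range(structure.n_atoms) if params.charge[i] > 0]
    cations = Selection("formal charge > 0", frozenset(cation_idx))
    anions = Selection(
        "group == carboxyl and element == O",
        frozenset(
            i for i in carboxyl_sel.resolved if structure.atoms[i].element == "O"
        ),
    )
    protein_idx = sorted(structure.groups.get("protein", frozenset()))
    donor_candidates = [
        i for i in protein_idx if structure.atoms[i].element.upper() in ("N", "O")
    ]
    hydrogen_map = build_hydrogen_map(structure, donor_candidates)
    donors = Selection("protein N/O with attached H", frozenset(hydrogen_map))

    salt_frames: dict[str, set[int]] = {}
    hbond_frames: dict[str, set[int]] = {}
    for k in range(trajectory.n_frames):
        frame = trajectory.frames[k]
        if cations and anions:
            for ckey, _akey, _d in detect_salt_bridges(
                structure, frame, cations, anions, salt_bridge, params.charge
            ):
                salt_frames.setdefault(f"{ckey[2]}{ckey[1]}", set()).add(k)
        if donors and anions:
            for d, _h, _a in detect_hbonds(
                structure, frame, donors, anions, hbond, hydrogen_map
            ):
                atom = structure.atoms[d]
                hbond_frames.setdefault(
                    f"{atom.residue_name}{atom.residue_id}", set()
                ).add(k)

    probe_keys = [
        (chain, resid, resname)
        for chain, resid, resname in structure.residues()
        if resname.upper() in ("LYS", "ARG", "HIS", "GLN", "SER", "ASN", "GLY")
    ]
    probes = residue_selections(structure, probe_keys)
    contact_fractions: dict[str, float] = {}
    if carboxyl_sel and probes:
        table = contact_ratio_table(trajectory, probes, carboxyl_sel, contact)
        contact_fractions = {
            f"{row.residue[2]}{row.residue[1]}": row.fraction for row in table.rows
        }

    return DetectorOutputs(
        blocking=blocking,
        stacking=stacking_out,
        salt_bridge_frames={k: frozenset(v) for k, v in salt_frames.items()},
        hbond_frames={k: frozenset(v) for k, v in hbond_frames.items()},
        contact_fractions=contact_fractions,
    )


@dataclass
class RecoveryRow:
    quantity: str
    true_value: float
    detected_value: float
    abs_error: float
    tolerance: float

    @property
    def ok(self) -> bool:
        return self.abs_error <= self.tolerance


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow]

    @property
    def ok(self) -> bool:
        return all(r.ok for r in self.rows)

    @property
    def exit_status(self) -> int:
        return 0 if self.ok else 1

    def to_text(self) -> str:
        lines = [f"{'quantity':<40} {'true':>10} {'detected':>10} {'abs_err':>10}  ok"]
        for r in self.rows:
            lines.append(
                f"{r.quantity:<40} {r.true_value:>10.4f} {r.detected_value:>10.4f} "
                f"{r.abs_error:>10.4f}  {'yes' if r.ok else 'NO'}"
            )
        return "\n".join(lines)


def recovery_report(
    truth: GroundTruth,
    detected: DetectorOutputs,
    onset_tolerance_frames: float = 0.0,
    ratio_tolerance: float = 0.0,
    frame_set_tolerance: float = 0.0,
) -> RecoveryReport:
    """Compare detector outputs to ground truth.

    Onset errors are in frames, ratio errors as fractions, event frame sets
    by symmetric-difference size.  ``exit_status`` is nonzero when any error
    exceeds its tolerance.
    """
    rows: list[RecoveryRow] = []
    for channel_id, true_onset in truth.blocking_onset_frame.items():
        profile = detected.blocking.get(channel_id)
        if profile is None:
            continue
        if profile.onset is None:
            det_frame = math.inf if true_onset is not None else None
        else:
            det_frame = profile.onset * 1000.0 / truth.frame_spacing
        if true_onset is None and det_frame is None:
            err = 0.0
            true_v, det_v = -1.0, -1.0
        elif true_onset is None or det_frame is None or math.isinf(det_frame):
            err = math.inf
            true_v = -1.0 if true_onset is None else float(true_onset)
            det_v = -1.0
        else:
            err = abs(det_frame - true_onset)
            true_v, det_v = float(true_onset), float(det_frame)
        rows.append(
            RecoveryRow(
                quantity=f"blocking_onset_frame[{channel_id}]",
                true_value=true_v,
                detected_value=det_v,
                abs_error=err,
                tolerance=onset_tolerance_frames,
            )
        )
    for label, true_ratio in truth.stacking_ratio.items():
        det = detected.stacking.get(label)
        det_ratio = det.ratio if det is not None else 0.0
        rows.append(
            RecoveryRow(
                quantity=f"stacking_ratio[{label}]",
                true_value=true_ratio,
                detected_value=det_ratio,
                abs_error=abs(det_ratio - true_ratio),
                tolerance=ratio_tolerance,
            )
        )
    for name, true_map, det_map in (
        ("salt_bridge_frames", truth.salt_bridge_frames, detected.salt_bridge_frames),
        ("hbond_frames", truth.hbond_frames, detected.hbond_frames),
    ):
        for label, true_frames in true_map.items():
            det_frames = det_map.get(label, frozenset())
            err = float(len(true_frames ^ det_frames))
            rows.append(
                RecoveryRow(
                    quantity=f"{name}[{label}]",
                    true_value=float(len(true_frames)),
                    detected_value=float(len(det_frames)),
                    abs_error=err,
                    tolerance=frame_set_tolerance,
                )
            )
    return RecoveryReport(rows=rows)


def write_scenario(
    trajectory: Trajectory, truth: GroundTruth, out_dir
) -> dict[str, str]:
    """Write multi-model PDB, GRO topology and the JSON ground truth."""
    from .io import write_structure, write_trajectory

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory_pdb": str(out / "scenario.pdb"),
        "topology_gro": str(out / "scenario.gro"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_trajectory(trajectory, paths["trajectory_pdb"])
    write_structure(
        trajectory.topology.with_positions(trajectory.frames[0]),
        paths["topology_gro"],
    )
    Path(paths["ground_truth"]).write_text(truth.to_json() + "\n")
    return paths
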