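"""Channel-mouth definitions and occlusion statistics.

A channel mouth is the centroid of the Cα atoms of its lining residues; a
frame counts as blocked when any tube heavy atom comes within
``block_distance`` of that centroid.  The pooled statistic is the
duration-weighted blocked fraction across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Selection, Structure, Trajectory
from .selection import resolve_selection

__all__ = [
    "ChannelSpec",
    "BlockingProfile",
    "PooledBlocking",
    "ChannelError",
    "mouth_geometry",
    "is_blocked",
    "blocking_onset",
    "pool_blocked_fraction",
]

PS_PER_NS = 1000.0


class ChannelError(ValueError):
    """Channel definition or occlusion computation failure."""


@dataclass(frozen=True)
class ChannelSpec:
    """A named channel mouth: lining residues plus geometric thresholds."""

    id: str
    lining_residues: str  # selection expression
    mouth_radius: float = 0.35  # nm, reserved for the probe-disc criterion
    block_distance: float = 0.7  # nm

    def __post_init__(self) -> None:
        if self.mouth_radius <= 0 or self.block_distance <= 0:
            raise ChannelError("channel radii must be positive")


@dataclass
class BlockingProfile:
    """Per-run occlusion summary.

    ``onset`` and ``duration`` are in ns.  ``per_frame_flags`` is present
    when the profile was derived from a trajectory and absent when it was
    constructed directly from an onset (blocking then persists to the end
    by definition).
    """

    run_id: str
    duration: float
    onset: Optional[float]
    blocked_fraction: float
    per_frame_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ChannelError("duration must be positive")
        if self.onset is not None and self.onset > self.duration:
            raise ChannelError("onset cannot exceed duration")
        if not (0.0 <= self.blocked_fraction <= 1.0):
            raise ChannelError("blocked_fraction must lie in [0, 1]")
        if self.per_frame_flags is not None:
            self.per_frame_flags = np.asarray(self.per_frame_flags, dtype=bool)

    @classmethod
    def from_onset(
        cls, run_id: str, duration: float, onset: Optional[float]
    ) -> "BlockingProfile":
        """Profile for a run whose blocking starts at ``onset`` ns and
        persists to the end (``onset=None`` means never blocked)."""
        if onset is None:
            frac = 0.0
        else:
            if onset < 0:
                raise ChannelError("onset must be non-negative")
            frac = (duration - onset) / duration
        return cls(run_id=run_id, duration=duration, onset=onset, blocked_fraction=frac)


@dataclass
class PooledBlocking:
    profiles: list[BlockingProfile]
    pooled_fraction: float

    @property
    def pooled_percent(self) -> float:
        return 100.0 * self.pooled_fraction


def mouth_geometry(
    frame: np.ndarray, protein: Structure, channel: ChannelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Mouth centroid (mean lining Cα) and outward unit vector.

    ``frame`` holds the coordinates to use (same atom order as ``protein``);
    the outward vector points from the protein's center of geometry through
    the centroid.  The protein body is group ``protein`` when registered,
    otherwise every atom outside groups ``cnt``/``carboxyl``.
    """
    frame = np.asarray(frame, dtype=float)
    lining = resolve_selection(protein, channel.lining_residues)
    ca = [
        i
        for i in sorted(lining.resolved)
        if protein.atoms[i].name.upper() == "CA"
    ]
    residues = {
        (protein.atoms[i].chain_id, protein.atoms[i].residue_id) for i in ca
    }
    if len(residues) < 3:
        raise ChannelError(
            f"channel {channel.id!r}: lining must resolve to >=3 residues with "
            f"Calpha atoms, got {len(residues)}"
        )
    centroid = frame[ca].mean(axis=0)
    if "protein" in protein.groups:
        body = sorted(protein.groups["protein"])
    else:
        excluded = protein.groups.get("cnt", frozenset()) | protein.groups.get(
            "carboxyl", frozenset()
        )
        body = [i for i in range(protein.n_atoms) if i not in excluded]
    cog = frame[body].mean(axis=0)
    outward = centroid - cog
    norm = np.linalg.norm(outward)
    if norm < 1e-9:
        raise ChannelError(
            f"channel {channel.id!r}: mouth centroid coincides with the protein "
            "center; outward direction undefined"
        )
    return centroid, outward / norm


def is_blocked(
    frame: np.ndarray,
    structure: Structure,
    channel: ChannelSpec,
    tube_atoms: Selection,
) -> bool:
    """True iff any tube heavy atom is within ``block_distance`` of the mouth."""
    if not tube_atoms:
        raise ChannelError("empty tube selection")
    centroid, _ = mouth_geometry(frame, structure, channel)
    idx = tube_atoms.indices()
    heavy = np.array([structure.atoms[i].is_heavy for i in idx], dtype=bool)
    idx = idx[heavy]
    if len(idx) == 0:
        raise ChannelError("tube selection contains no heavy atoms")
    d = np.linalg.norm(np.asarray(frame)[idx] - centroid, axis=1)
    return bool(d.min() <= channel.block_distance)


def blocked_flags(
    trajectory: Trajectory, channel: ChannelSpec, tube_atoms: Selection
) -> np.ndarray:
    return np.array(
        [
            is_blocked(trajectory.frames[k], trajectory.topology, channel, tube_atoms)
            for k in range(trajectory.n_frames)
        ],
        dtype=bool,
    )


def blocking_onset(
    trajectory: Trajectory,
    channel: ChannelSpec,
    tube_atoms: Selection,
    persistence: float = 1.0,
    run_id: str = "run",
) -> BlockingProfile:
    """Earliest time from which the blocked-frame fraction of the remaining
    run is at least ``persistence``; None when no such time exists."""
    if not (0.0 < persistence <= 1.0):
        raise ChannelError(f"persistence must lie in (0, 1], got {persistence}")
    flags = blocked_flags(trajectory, channel, tube_atoms)
    n = len(flags)
    suffix_blocked = np.cumsum(flags[::-1])[::-1]
    onset = None
    for k in range(n):
        remaining = n - k
        if suffix_blocked[k] / remaining >= persistence:
            onset = (trajectory.times[k] - trajectory.times[0]) / PS_PER_NS
            break
    duration = trajectory.duration / PS_PER_NS
    return BlockingProfile(
        run_id=run_id,
        duration=duration,
        onset=onset,
        blocked_fraction=float(flags.sum()) / n,
        per_frame_flags=flags,
    )


def pool_blocked_fraction(profiles: Sequence[BlockingProfile]) -> PooledBlocking:
    """Duration-weighted pooled blocked fraction across runs.

    Equals total blocked time over total simulated time; for onset-style
    profiles this is sum(duration_i - onset_i) / sum(duration_i), with runs
    that never block contributing zero blocked time.
    """
    profiles = list(profiles)
    if not profiles:
        raise ChannelError("cannot pool an empty profile list")
    total = sum(p.duration for p in profiles)
    blocked = sum(p.blocked_fraction * p.duration for p in profiles)
    return PooledBlocking(profiles=profiles, pooled_fraction=blocked / total)
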