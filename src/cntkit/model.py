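"""Core domain types: atoms, structures, trajectories and selections.

All in-memory coordinates are in nanometres, times in picoseconds, energies
in kJ/mol and charges in units of the elementary charge.  File readers and
writers convert at the boundary (PDB is in angstroms).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "StructureError",
]


class StructureError(ValueError):
    """Raised when a structure or trajectory violates its invariants."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus a position in nm.

    ``index`` is the 0-based position of the atom inside its Structure;
    ``residue_id`` is preserved exactly as found in the input file
    (1-based in typical PDB/GRO files).
    """

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.index} ({self.name}): empty element")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"atom {self.index} ({self.name}): position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", tuple(float(x) for x in pos))

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def moved_to(self, position: Sequence[float]) -> "AtomRecord":
        return replace(self, position=tuple(float(x) for x in position))


@dataclass
class Structure:
    """An ordered collection of atoms with optional box and named groups.

    ``groups`` maps a name (e.g. ``"cnt"``, ``"protein"``, ``"carboxyl"``)
    to a frozen set of atom indices; selections can refer to them with
    ``group == name``.
    """

    atoms: list[AtomRecord]
    box: Optional[tuple[float, float, float]] = None
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure must contain at least 1 atom (zero atoms)")
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise StructureError(
                    f"atom indices must be 0-based and contiguous; "
                    f"found index {atom.index} at position {i}"
                )
        n = len(self.atoms)
        self.groups = {k: frozenset(v) for k, v in self.groups.items()}
        for name, members in self.groups.items():
            bad = [i for i in members if not (0 <= i < n)]
            if bad:
                raise StructureError(f"group {name!r} refers to invalid indices {bad[:5]}")
        seen: dict[tuple[str, int], str] = {}
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_id)
            prev = seen.setdefault(key, atom.residue_name)
            if prev != atom.residue_name:
                raise StructureError(
                    f"residue {key} has inconsistent names {prev!r} / {atom.residue_name!r}"
                )
        if self.box is not None:
            box = tuple(float(x) for x in self.box)
            if len(box) != 3 or any(x <= 0 for x in box):
                raise StructureError(f"box must be 3 positive lengths, got {self.box}")
            self.box = box

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm (a fresh copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def with_positions(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        atoms = [a.moved_to(coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, box=self.box, groups=dict(self.groups))

    def with_groups(self, **groups: Iterable[int]) -> "Structure":
        merged = dict(self.groups)
        merged.update({k: frozenset(v) for k, v in groups.items()})
        return Structure(atoms=list(self.atoms), box=self.box, groups=merged)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_id, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        last = None
        for a in self.atoms:
            key = (a.chain_id, a.residue_id, a.residue_name)
            if key != last:
                if key not in out:
                    out.append(key)
                last = key
        return out

    def atoms_of_residue(self, chain_id: str, residue_id: int) -> list[int]:
        return [
            a.index
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_id == residue_id
        ]


@dataclass
class Trajectory:
    """Frames of coordinates (nm) over a fixed topology, timestamped in ps."""

    topology: Structure
    times: np.ndarray
    frames: np.ndarray
    times_synthesized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory must contain at least 1 frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise StructureError(
                f"times length {self.times.shape} does not match "
                f"{self.frames.shape[0]} frames"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @property
    def frame_spacing(self) -> float:
        """Median inter-frame spacing in ps (1.0 for a single frame)."""
        if self.n_frames < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Total simulated span in ps, counting each frame as one spacing."""
        return self.n_frames * self.frame_spacing

    def __iter__(self):
        return iter(self.frames)


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression plus the index set.

    An empty resolution is a legitimate value, distinguishable from a
    resolution error (which raises).
    """

    expression: str
    resolved: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "resolved", frozenset(int(i) for i in self.resolved))

    def indices(self) -> np.ndarray:
        """Sorted index array, convenient for numpy fancy indexing."""
        return np.array(sorted(self.resolved), dtype=int)

    def __len__(self) -> int:
        return len(self.resolved)

    def __bool__(self) -> bool:
        return len(self.resolved) > 0
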