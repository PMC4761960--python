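"""Readers and writers for PDB and GRO structures and multi-frame trajectories.

Coordinates are converted to nm at this boundary (PDB files are in angstrom,
GRO files already in nm).  The fixed-width writers refuse to truncate names
silently; over-long fields are an error.  PDB atom serials beyond 99999 are
written (and read back) in upper-case hexadecimal, a convention shared with
several MD visualisation tools.
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .model import AtomRecord, Structure, StructureError, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "FileFormatError",
]

A_PER_NM = 10.0

_ELEMENTS_2 = {
    "HE", "LI", "BE", "NE", "NA", "MG", "AL", "SI", "CL", "AR", "CA", "SC",
    "TI", "CR", "MN", "FE", "CO", "NI", "CU", "ZN", "SE", "BR", "KR", "RB",
    "SR", "MO", "AG", "CD", "SN", "SB", "TE", "XE", "CS", "BA", "PT", "AU",
    "HG", "PB",
}


class FileFormatError(ValueError):
    """Raised for unreadable, malformed or unwritable structure files."""


def _infer_format(path: os.PathLike, format: Optional[str]) -> str:
    if format:
        return format.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"pdb", "gro", "xtc", "dcd"}:
        return suffix
    raise FileFormatError(f"cannot infer format from {path}; pass format= explicitly")


def _element_from_name(raw_name_field: str) -> str:
    """Infer the element from a PDB atom-name field.

    Follows the left-justification rule: a two-letter element occupies
    columns 13-14 (so the raw field does not start with a blank); otherwise
    the element is the first alphabetic character of the stripped name.
    Nanotube carbons (names like C, C12) resolve to C either way.
    """
    stripped = raw_name_field.strip()
    if not stripped:
        raise FileFormatError("empty atom name")
    if len(raw_name_field) >= 2 and raw_name_field[0] not in (" ", ""):
        two = raw_name_field[:2].strip().upper()
        if two in _ELEMENTS_2:
            return two[0] + two[1].lower()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise FileFormatError(f"cannot infer element from atom name {stripped!r}")


def _parse_serial(text: str, lineno: int) -> int:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        try:
            return int(text, 16)
        except ValueError:
            raise FileFormatError(
                f"line {lineno}: malformed atom serial {text!r}"
            ) from None


def _parse_pdb_atom_line(line: str, lineno: int, index: int) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise FileFormatError(
            f"line {lineno}: ATOM/HETATM record shorter than coordinate columns"
        )
    try:
        raw_name = line[12:16]
        name = raw_name.strip()
        residue_name = line[17:21].strip()
        chain_id = line[21].strip() or "A"
        residue_id = _parse_serial(line[22:26], lineno)
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FileFormatError(f"line {lineno}: malformed fixed-width PDB line: {exc}")
    element_field = line[76:78].strip() if len(line) >= 78 else ""
    if element_field:
        element = element_field[0].upper() + element_field[1:].lower()
    else:
        element = _element_from_name(raw_name)
    return AtomRecord(
        index=index,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_id=residue_id,
        chain_id=chain_id,
        position=(x / A_PER_NM, y / A_PER_NM, z / A_PER_NM),
    )


def _read_pdb(path: Path) -> Structure:
    atoms: list[AtomRecord] = []
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record in ("ATOM  ", "HETATM"):
                atoms.append(_parse_pdb_atom_line(line, lineno, len(atoms)))
            elif record == "CRYST1":
                try:
                    box = (
                        float(line[6:15]) / A_PER_NM,
                        float(line[15:24]) / A_PER_NM,
                        float(line[24:33]) / A_PER_NM,
                    )
                except ValueError:
                    raise FileFormatError(f"line {lineno}: malformed CRYST1 record")
            elif record.startswith("ENDMDL") and atoms:
                break  # single-structure read: first model only
    if not atoms:
        raise FileFormatError(f"{path}: zero atoms")
    return Structure(atoms=atoms, box=box)


def _read_gro(path: Path) -> Structure:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise FileFormatError(f"{path}: zero atoms")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise FileFormatError("line 2: expected atom count in GRO file")
    if n_atoms < 1:
        raise FileFormatError(f"{path}: zero atoms")
    if len(lines) < 2 + n_atoms:
        raise FileFormatError(
            f"{path}: atom count {n_atoms} exceeds available lines"
        )
    atoms: list[AtomRecord] = []
    for i in range(n_atoms):
        line = lines[2 + i]
        lineno = 3 + i
        try:
            residue_id = int(line[0:5])
            residue_name = line[5:10].strip()
            raw_name = line[10:15]
            name = raw_name.strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise FileFormatError(f"line {lineno}: malformed GRO line: {exc}")
        element = _element_from_name(name)
        atoms.append(
            AtomRecord(
                index=i,
                name=name,
                element=element,
                residue_name=residue_name,
                residue_id=residue_id,
                chain_id="A",
                position=(x, y, z),
            )
        )
    box = None
    if len(lines) > 2 + n_atoms:
        fields = lines[2 + n_atoms].split()
        if len(fields) >= 3:
            candidate = (float(fields[0]), float(fields[1]), float(fields[2]))
            if any(v > 0 for v in candidate):
                box = candidate
    return Structure(atoms=atoms, box=box)


def read_structure(path: os.PathLike | str, format: Optional[str] = None) -> Structure:
    """Read a single structure from a PDB or GRO file (coordinates in nm)."""
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"unreadable file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "gro":
        return _read_gro(path)
    raise FileFormatError(f"unsupported structure format {fmt!r}")


def _format_serial(value: int, width: int) -> str:
    if value < 10**width:
        return f"{value:>{width}d}"
    if value < 16**width:
        return f"{value:>{width}X}"
    raise FileFormatError(f"serial {value} does not fit in {width} columns")


def _pdb_atom_line(atom: AtomRecord, serial: int) -> str:
    if len(atom.name) > 4:
        raise FileFormatError(
            f"atom name {atom.name!r} exceeds 4 characters; cannot write PDB "
            "without truncation"
        )
    if len(atom.residue_name) > 4:
        raise FileFormatError(
            f"residue name {atom.residue_name!r} exceeds 4 characters; cannot "
            "write PDB without truncation"
        )
    if len(atom.chain_id) > 1:
        raise FileFormatError(f"chain id {atom.chain_id!r} exceeds 1 character")
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
    x, y, z = (c * A_PER_NM for c in atom.position)
    if not all(-999.999 <= v <= 9999.999 for v in (x, y, z)):
        raise FileFormatError(f"coordinate out of PDB fixed-width range: {(x, y, z)}")
    return (
        f"ATOM  {_format_serial(serial, 5)} {name:<4} {atom.residue_name:<4}"
        f"{atom.chain_id:1}{_format_serial(atom.residue_id, 4)}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2}\n"
    )


def _write_pdb(structure: Structure, path: Path) -> None:
    lines = []
    if structure.box is not None:
        a, b, c = (v * A_PER_NM for v in structure.box)
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n"
        )
    for atom in structure.atoms:
        lines.append(_pdb_atom_line(atom, atom.index + 1))
    lines.append("END\n")
    path.write_text("".join(lines))


def _write_gro(structure: Structure, path: Path) -> None:
    lines = ["written by cntkit\n", f"{structure.n_atoms:5d}\n"]
    for atom in structure.atoms:
        if len(atom.name) > 5:
            raise FileFormatError(
                f"atom name {atom.name!r} exceeds 5 characters for GRO"
            )
        if len(atom.residue_name) > 5:
            raise FileFormatError(
                f"residue name {atom.residue_name!r} exceeds 5 characters for GRO"
            )
        x, y, z = atom.position
        lines.append(
            f"{atom.residue_id % 100000:5d}{atom.residue_name:<5s}"
            f"{atom.name:>5s}{(atom.index + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    box = structure.box or (0.0, 0.0, 0.0)
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")
    path.write_text("".join(lines))


def write_structure(
    structure: Structure, path: os.PathLike | str, format: Optional[str] = None
) -> None:
    """Write a structure to PDB or GRO; round trips positions within 1e-3 nm."""
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            _write_pdb(structure, path)
        elif fmt == "gro":
            _write_gro(structure, path)
        else:
            raise FileFormatError(f"unsupported structure format {fmt!r}")
    except OSError as exc:
        raise FileFormatError(f"unwritable path {path}: {exc}") from exc


_TIME_REMARK = "REMARK 250 TIME_PS"


def _read_multimodel_pdb(topology: Structure, path: Path) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    current: list[tuple[float, float, float]] | None = None
    current_time: float | None = None
    saw_model = False

    def _close_frame() -> None:
        nonlocal current, current_time
        if current is None:
            return
        k = len(frames)
        if len(current) != topology.n_atoms:
            raise FileFormatError(
                f"atom-count mismatch at frame {k}: topology has "
                f"{topology.n_atoms} atoms, frame has {len(current)}"
            )
        frames.append(np.asarray(current, dtype=float))
        times.append(current_time if current_time is not None else float("nan"))
        current = None
        current_time = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model = True
                _close_frame()
                current = []
            elif record in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                try:
                    xyz = (
                        float(line[30:38]) / A_PER_NM,
                        float(line[38:46]) / A_PER_NM,
                        float(line[46:54]) / A_PER_NM,
                    )
                except (ValueError, IndexError):
                    raise FileFormatError(
                        f"line {lineno}: malformed fixed-width PDB line"
                    )
                current.append(xyz)
            elif line.startswith(_TIME_REMARK):
                try:
                    current_time = float(line[len(_TIME_REMARK):].strip())
                except ValueError:
                    raise FileFormatError(f"line {lineno}: malformed time remark")
            elif record.startswith("ENDMDL"):
                _close_frame()
    _close_frame()
    if not frames:
        raise FileFormatError(f"{path}: no frames")
    time_arr = np.asarray(times, dtype=float)
    synthesized = bool(np.any(np.isnan(time_arr)))
    if synthesized:
        time_arr = np.arange(len(frames), dtype=float)
    del saw_model
    return Trajectory(
        topology=topology,
        times=time_arr,
        frames=np.stack(frames),
        times_synthesized=synthesized,
    )


def _read_mdanalysis_trajectory(topology: Structure, path: Path, fmt: str) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FileFormatError(
            f"reading {fmt.upper()} requires the MDAnalysis library"
        ) from exc
    universe = mda.Universe.empty(topology.n_atoms, trajectory=True)
    universe.load_new(str(path))
    frames, times = [], []
    synthesized = False
    for ts in universe.trajectory:
        if ts.positions.shape[0] != topology.n_atoms:
            raise FileFormatError(
                f"atom-count mismatch at frame {ts.frame}: topology has "
                f"{topology.n_atoms} atoms, frame has {ts.positions.shape[0]}"
            )
        frames.append(ts.positions.astype(float) / A_PER_NM)
        t = getattr(ts, "time", None)
        if t is None:
            synthesized = True
            t = float(len(times))
        times.append(float(t))
    if not frames:
        raise FileFormatError(f"{path}: no frames")
    return Trajectory(
        topology=topology,
        times=np.asarray(times),
        frames=np.stack(frames),
        times_synthesized=synthesized,
    )


def read_trajectory(
    topology: Structure, path: os.PathLike | str, format: Optional[str] = None
) -> Trajectory:
    """Read a multi-frame trajectory over ``topology``.

    Multi-model PDB is parsed natively; XTC/DCD are delegated to MDAnalysis
    when it is installed.  Missing timestamps are synthesized as 0,1,2,... ps
    and flagged via ``Trajectory.times_synthesized``.
    """
    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"unreadable file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_multimodel_pdb(topology, path)
    if fmt in ("xtc", "dcd"):
        return _read_mdanalysis_trajectory(topology, path, fmt)
    raise FileFormatError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(trajectory: Trajectory, path: os.PathLike | str) -> None:
    """Write a trajectory as a multi-model PDB with per-model time remarks."""
    path = Path(path)
    lines: list[str] = []
    topo = trajectory.topology
    for k in range(trajectory.n_frames):
        lines.append(f"MODEL     {k + 1:>4d}\n")
        lines.append(f"{_TIME_REMARK} {trajectory.times[k]:.6f}\n")
        coords = trajectory.frames[k]
        for atom in topo.atoms:
            lines.append(_pdb_atom_line(atom.moved_to(coords[atom.index]), atom.index + 1))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    path.write_text("".join(lines))
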