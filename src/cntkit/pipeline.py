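"""Config-driven orchestration: load systems, run every analysis over one or
more trajectory runs, pool the channel statistics and emit a report.

The report JSON is fully deterministic for a given config + inputs: every
effective parameter (including defaulted cutoffs) is echoed into it, and
wall-clock metadata is segregated into a sidecar file.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builder import TubeLattice, assign_nonbonded_params, find_hexagons
from .energetics import interaction_energy_series, rmsd_series
from .fingerprints import (
    ContactCriteria,
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
from .io import FileFormatError, read_structure, read_trajectory
from .model import Selection, Structure, Trajectory
from .occlusion import (
    BlockingProfile,
    ChannelSpec,
    blocking_onset,
    pool_blocked_fraction,
)
from .selection import resolve_selection
from .synthetic import build_hydrogen_map

__all__ = ["AnalysisConfig", "ConfigError", "run_analysis", "load_config"]

log = logging.getLogger("cntkit.pipeline")

_PROBE_RESNAMES = ("LYS", "ARG", "HIS", "GLN", "SER", "ASN", "GLY")


class ConfigError(ValueError):
    pass


@dataclass
class RunSpec:
    id: str
    trajectory: str
    format: Optional[str] = None


@dataclass
class AnalysisConfig:
    topology: str
    runs: list[RunSpec]
    output_dir: str
    topology_format: Optional[str] = None
    protein_selection: str = "group == protein"
    tube_selection: str = "group == cnt"
    carboxyl_selection: str = "group == carboxyl"
    channels: list[ChannelSpec] = field(default_factory=list)
    contact: ContactCriteria = field(default_factory=ContactCriteria)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    salt_bridge: SaltBridgeCriteria = field(default_factory=SaltBridgeCriteria)
    stacking: StackingCriteria = field(default_factory=StackingCriteria)
    energy_cutoff: float = 1.0
    rmsd_reference: int = 0
    rmsd_selection: str = "name == CA"
    persistence: float = 1.0
    parameter_table: str = "simple_v1"
    external_blocking: dict[str, list[dict[str, Any]]] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def echo(self) -> dict[str, Any]:
        """Every effective parameter, defaults included, for the report."""
        out = {
            "topology": self.topology,
            "topology_format": self.topology_format,
            "runs": [asdict(r) for r in self.runs],
            "output_dir": self.output_dir,
            "selections": {
                "protein": self.protein_selection,
                "tube": self.tube_selection,
                "carboxyl": self.carboxyl_selection,
            },
            "channels": [
                {
                    "id": c.id,
                    "lining_residues": c.lining_residues,
                    "mouth_radius": c.mouth_radius,
                    "block_distance": c.block_distance,
                }
                for c in self.channels
            ],
            "criteria": {
                "contact": asdict(self.contact),
                "hbond": asdict(self.hbond),
                "salt_bridge": asdict(self.salt_bridge),
                "stacking": {
                    **asdict(self.stacking),
                    "tshape_angle_range": list(self.stacking.tshape_angle_range),
                },
            },
            "energy_cutoff": self.energy_cutoff,
            "rmsd_reference": self.rmsd_reference,
            "rmsd_selection": self.rmsd_selection,
            "persistence": self.persistence,
            "parameter_table": self.parameter_table,
            "external_blocking": self.external_blocking,
            "seed": self.seed,
        }
        return out


def _criteria_from(d: dict[str, Any], cls, **renames):
    kwargs = dict(d)
    if cls is StackingCriteria and "tshape_angle_range" in kwargs:
        kwargs["tshape_angle_range"] = tuple(kwargs["tshape_angle_range"])
    return cls(**kwargs)


def load_config(path) -> AnalysisConfig:
    """Load an analysis config from a YAML file; relative paths are taken
    relative to the config file's directory."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    base = path.parent

    def _resolve(p: str) -> str:
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    try:
        runs = [
            RunSpec(
                id=str(r.get("id", f"run{i + 1}")),
                trajectory=_resolve(r["trajectory"]),
                format=r.get("format"),
            )
            for i, r in enumerate(raw.get("runs", []))
        ]
        channels = [
            ChannelSpec(
                id=str(c["id"]),
                lining_residues=c["lining"],
                mouth_radius=float(c.get("mouth_radius", 0.35)),
                block_distance=float(c.get("block_distance", 0.7)),
            )
            for c in raw.get("channels", [])
        ]
        criteria = raw.get("criteria", {})
        selections = raw.get("selections", {})
        config = AnalysisConfig(
            topology=_resolve(raw["topology"]),
            topology_format=raw.get("topology_format"),
            runs=runs,
            output_dir=_resolve(raw.get("output_dir", "cntkit_out")),
            protein_selection=selections.get("protein", "group == protein"),
            tube_selection=selections.get("tube", "group == cnt"),
            carboxyl_selection=selections.get("carboxyl", "group == carboxyl"),
            channels=channels,
            contact=_criteria_from(criteria.get("contact", {}), ContactCriteria),
            hbond=_criteria_from(criteria.get("hbond", {}), HBondCriteria),
            salt_bridge=_criteria_from(criteria.get("salt_bridge", {}), SaltBridgeCriteria),
            stacking=_criteria_from(criteria.get("stacking", {}), StackingCriteria),
            energy_cutoff=float(raw.get("energy", {}).get("cutoff", 1.0)),
            rmsd_reference=int(raw.get("rmsd", {}).get("reference", 0)),
            rmsd_selection=raw.get("rmsd", {}).get("selection", "name == CA"),
            persistence=float(raw.get("persistence", 1.0)),
            parameter_table=raw.get("parameter_table", "simple_v1"),
            external_blocking=raw.get("external_blocking", {}),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )
    except KeyError as exc:
        raise ConfigError(f"config {path} missing required key: {exc}") from exc
    if not config.runs and not config.external_blocking:
        raise ConfigError("config declares no runs and no external blocking profiles")
    return config


def _register_groups(structure: Structure, config: AnalysisConfig) -> Structure:
    """Materialize the configured selections as named groups so that group
    expressions and parameter assignment work on plain file input."""

    def _safe(expr: str) -> frozenset[int]:
        try:
            return resolve_selection(structure, expr).resolved
        except Exception:
            return frozenset()

    cnt = _safe(config.tube_selection)
    carboxyl = _safe(config.carboxyl_selection)
    cnt = cnt - carboxyl
    protein = _safe(config.protein_selection)
    if not protein:
        protein = frozenset(range(structure.n_atoms)) - cnt - carboxyl
    if not cnt:
        raise ConfigError(
            f"tube selection {config.tube_selection!r} resolves to no atoms"
        )
    return structure.with_groups(cnt=cnt, carboxyl=carboxyl, protein=protein)


def _analyze_run(
    run: RunSpec,
    topology: Structure,
    lattice: TubeLattice,
    params,
    config: AnalysisConfig,
) -> dict[str, Any]:
    trajectory = read_trajectory(topology, run.trajectory, run.format)
    structure = trajectory.topology
    protein_sel = Selection("group == protein", structure.groups["protein"])
    tube_all = Selection(
        "tube + carboxyl",
        structure.groups["cnt"] | structure.groups.get("carboxyl", frozenset()),
    )
    carboxyl_sel = Selection("group == carboxyl", structure.groups.get("carboxyl", frozenset()))
    anions = Selection(
        "carboxyl oxygens",
        frozenset(i for i in carboxyl_sel.resolved if structure.atoms[i].element == "O"),
    )
    cations = Selection(
        "formal cations",
        frozenset(i for i in protein_sel.resolved if params.charge[i] > 0),
    )
    donor_candidates = [
        i
        for i in sorted(protein_sel.resolved)
        if structure.atoms[i].element.upper() in ("N", "O")
    ]
    hydrogen_map = build_hydrogen_map(structure, donor_candidates)
    donors = Selection("protein donors", frozenset(hydrogen_map))
    rings = aromatic_rings(structure)

    n_contacts = np.zeros(trajectory.n_frames, dtype=int)
    n_hbonds = np.zeros(trajectory.n_frames, dtype=int)
    n_bridges = np.zeros(trajectory.n_frames, dtype=int)
    n_stacks = np.zeros(trajectory.n_frames, dtype=int)
    for k in range(trajectory.n_frames):
        frame = trajectory.frames[k]
        n_contacts[k] = contact_count(structure, frame, protein_sel, tube_all, config.contact)
        if donors and anions:
            n_hbonds[k] = len(
                detect_hbonds(structure, frame, donors, anions, config.hbond, hydrogen_map)
            )
        if cations and anions:
            n_bridges[k] = len(
                detect_salt_bridges(
                    structure, frame, cations, anions, config.salt_bridge, params.charge
                )
            )
        if rings:
            n_stacks[k] = len(
                detect_pi_stacking(structure, frame, rings, lattice, config.stacking, k)
            )

    energy = interaction_energy_series(
        trajectory, protein_sel, tube_all, params, config.energy_cutoff
    )
    rmsd_sel = resolve_selection(structure, config.rmsd_selection)
    rmsd_sel = Selection(
        config.rmsd_selection, rmsd_sel.resolved & protein_sel.resolved
    )
    rmsd = rmsd_series(trajectory, config.rmsd_reference, rmsd_sel)

    blocking: dict[str, BlockingProfile] = {}
    for channel in config.channels:
        blocking[channel.id] = blocking_onset(
            trajectory, channel, tube_all, config.persistence, run_id=run.id
        )

    stacking_ratios = {}
    for ring in rings:
        chain, resid, resname = ring.residue
        ratio = stacking_formation_ratio(trajectory, ring.residue, lattice, config.stacking)
        stacking_ratios[f"{resname}{resid}"] = {
            "ratio": ratio.ratio,
            "parallel": ratio.parallel_fraction,
            "tshape": ratio.tshape_fraction,
            "persistent": ratio.persistent,
        }

    probe_keys = [
        (chain, resid, resname)
        for chain, resid, resname in structure.residues()
        if resname.upper() in _PROBE_RESNAMES and resid in
        {structure.atoms[i].residue_id for i in protein_sel.resolved}
    ]
    contact_ratios = {}
    if anions and probe_keys:
        table = contact_ratio_table(
            trajectory, residue_selections(structure, probe_keys), anions, config.contact
        )
        contact_ratios = {
            f"{row.residue[2]}{row.residue[1]}": {
                "fraction": row.fraction,
                "persistent": row.persistent,
            }
            for row in table.rows
        }

    series = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ps": trajectory.times,
            "contacts": n_contacts,
            "hbonds": n_hbonds,
            "salt_bridges": n_bridges,
            "stacks": n_stacks,
            "vdw_kJmol": energy.vdw,
            "coulomb_kJmol": energy.coulomb,
            "vdw_kcalmol": energy.vdw_kcal,
            "coulomb_kcalmol": energy.coulomb_kcal,
            "rmsd_nm": rmsd.rmsd,
        }
    )
    return {
        "trajectory": trajectory,
        "series": series,
        "blocking": blocking,
        "stacking_ratios": stacking_ratios,
        "contact_ratios": contact_ratios,
    }


def _profile_payload(profile: BlockingProfile) -> dict[str, Any]:
    return {
        "run_id": profile.run_id,
        "duration_ns": profile.duration,
        "onset_ns": profile.onset,
        "blocked_fraction": profile.blocked_fraction,
    }


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the configured analyses and write report + series files.

    Deterministic for fixed config and inputs; any unreadable input aborts
    with an error naming the cause rather than silently omitting a run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    topology = read_structure(config.topology, config.topology_format)
    topology = _register_groups(topology, config)
    cnt_indices = sorted(topology.groups["cnt"])
    hexagons = find_hexagons(topology.positions, indices=cnt_indices)
    lattice = TubeLattice(
        cnt_indices=tuple(cnt_indices), hexagons=hexagons, rim_indices=()
    )
    params = assign_nonbonded_params(topology, config.parameter_table)

    report: dict[str, Any] = {
        "software": {"name": "cntkit", "version": __version__},
        "config": config.echo(),
        "runs": {},
        "pooled_blocking": {},
    }
    profiles_by_channel: dict[str, list[BlockingProfile]] = {
        c.id: [] for c in config.channels
    }
    for channel_id in config.external_blocking:
        profiles_by_channel.setdefault(channel_id, [])

    for run in config.runs:
        log.info("analyzing run %s (%s)", run.id, run.trajectory)
        result = _analyze_run(run, topology, lattice, params, config)
        series_path = out_dir / f"series_{run.id}.tsv"
        result["series"].to_csv(series_path, sep="\t", index=False, float_format="%.6f")
        for channel_id, profile in result["blocking"].items():
            profiles_by_channel[channel_id].append(profile)
        report["runs"][run.id] = {
            "n_frames": int(result["trajectory"].n_frames),
            "duration_ns": result["trajectory"].duration / 1000.0,
            "series_file": series_path.name,
            "blocking": {
                cid: _profile_payload(p) for cid, p in result["blocking"].items()
            },
            "stacking_ratios": result["stacking_ratios"],
            "contact_ratios": result["contact_ratios"],
        }

    for channel_id, externals in config.external_blocking.items():
        for i, entry in enumerate(externals):
            if "flags" in entry:
                flags = np.asarray(entry["flags"], dtype=bool)
                spacing_ns = float(entry.get("frame_spacing_ns", 1.0))
                onset = None
                for k in range(len(flags)):
                    if flags[k:].all():
                        onset = k * spacing_ns
                        break
                profile = BlockingProfile(
                    run_id=str(entry.get("run_id", f"external{i + 1}")),
                    duration=len(flags) * spacing_ns,
                    onset=onset,
                    blocked_fraction=float(flags.sum()) / len(flags),
                    per_frame_flags=flags,
                )
            else:
                profile = BlockingProfile.from_onset(
                    run_id=str(entry.get("run_id", f"external{i + 1}")),
                    duration=float(entry["duration_ns"]),
                    onset=entry.get("onset_ns"),
                )
            profiles_by_channel[channel_id].append(profile)

    for channel_id, profiles in profiles_by_channel.items():
        if not profiles:
            continue
        pooled = pool_blocked_fraction(profiles)
        report["pooled_blocking"][channel_id] = {
            "pooled_fraction": pooled.pooled_fraction,
            "pooled_percent": pooled.pooled_percent,
            "profiles": [_profile_payload(p) for p in pooled.profiles],
        }

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_sidecar(out_dir)
    log.info("report written to %s", report_path)
    return report


def _write_sidecar(out_dir: Path) -> None:
    """Wall-clock metadata lives here so report.json stays byte-stable."""
    import datetime

    meta = {"written_at": datetime.datetime.now().isoformat()}
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
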