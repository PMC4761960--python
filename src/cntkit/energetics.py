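"""Pairwise 12-6 Lennard-Jones / Coulomb interaction energies and Kabsch RMSD.

These are post-hoc vacuum pair sums with plain cutoff truncation — no mesh
summation and no reaction field — so absolute Coulomb values are comparable
to engine output only in trend.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import NonbondedParams
from .model import Selection, Trajectory

__all__ = [
    "EnergySeries",
    "RmsdSeries",
    "EnergeticsError",
    "COULOMB_CONSTANT",
    "KJ_PER_KCAL",
    "lj_pair",
    "coulomb_pair",
    "interaction_energy_series",
    "kabsch_rotation",
    "rmsd_series",
]

COULOMB_CONSTANT = 138.935458  # kJ mol^-1 nm e^-2
KJ_PER_KCAL = 4.184


class EnergeticsError(ValueError):
    pass


@dataclass
class EnergySeries:
    times: np.ndarray  # ps
    vdw: np.ndarray  # kJ/mol
    coulomb: np.ndarray  # kJ/mol

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        self.coulomb = np.asarray(self.coulomb, dtype=float)
        if not (len(self.times) == len(self.vdw) == len(self.coulomb)):
            raise EnergeticsError("series lengths disagree")
        if not (np.all(np.isfinite(self.vdw)) and np.all(np.isfinite(self.coulomb))):
            raise EnergeticsError("energy series contains non-finite values")

    @property
    def vdw_kcal(self) -> np.ndarray:
        return self.vdw / KJ_PER_KCAL

    @property
    def coulomb_kcal(self) -> np.ndarray:
        return self.coulomb / KJ_PER_KCAL


@dataclass
class RmsdSeries:
    times: np.ndarray  # ps
    rmsd: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if len(self.times) != len(self.rmsd):
            raise EnergeticsError("series lengths disagree")
        if np.any(self.rmsd < 0):
            raise EnergeticsError("rmsd must be non-negative")


def lj_pair(r: float, pi: tuple[float, float], pj: tuple[float, float]) -> float:
    """12-6 energy at separation ``r`` nm for atoms with (epsilon, sigma)
    ``pi`` and ``pj``, combined by Lorentz-Berthelot rules."""
    if r <= 0:
        raise EnergeticsError(f"separation must be positive, got {r}")
    eps = np.sqrt(pi[0] * pj[0])
    sig = 0.5 * (pi[1] + pj[1])
    x6 = (sig / r) ** 6
    return float(4.0 * eps * (x6 * x6 - x6))


def coulomb_pair(r: float, qi: float, qj: float) -> float:
    """Vacuum Coulomb energy (kJ/mol) between charges ``qi``/``qj`` e at r nm."""
    if r <= 0:
        raise EnergeticsError(f"separation must be positive, got {r}")
    return COULOMB_CONSTANT * qi * qj / r


def interaction_energy_series(
    trajectory: Trajectory,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
    cutoff: float = 1.0,
) -> EnergySeries:
    """Cross-group LJ + Coulomb sums per frame, truncated at ``cutoff`` nm."""
    if cutoff <= 0:
        raise EnergeticsError("cutoff must be positive")
    ia = group_a.indices()
    ib = group_b.indices()
    if len(ia) == 0 or len(ib) == 0:
        raise EnergeticsError("energy groups must be non-empty")
    if group_a.resolved & group_b.resolved:
        raise EnergeticsError("energy groups overlap")
    if params.n_atoms < trajectory.n_atoms:
        raise EnergeticsError(
            f"parameters cover {params.n_atoms} atoms but trajectory has "
            f"{trajectory.n_atoms}"
        )
    eps_a, eps_b = params.epsilon[ia], params.epsilon[ib]
    sig_a, sig_b = params.sigma[ia], params.sigma[ib]
    q_a, q_b = params.charge[ia], params.charge[ib]
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    qq = np.outer(q_a, q_b)

    vdw = np.zeros(trajectory.n_frames)
    coul = np.zeros(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        coords = trajectory.frames[k]
        d = np.linalg.norm(coords[ia][:, None, :] - coords[ib][None, :, :], axis=2)
        within = d <= cutoff
        if not within.any():
            continue
        r = d[within]
        x6 = (sig_ij[within] / r) ** 6
        vdw[k] = float(np.sum(4.0 * eps_ij[within] * (x6 * x6 - x6)))
        coul[k] = float(np.sum(COULOMB_CONSTANT * qq[within] / r))
    return EnergySeries(times=trajectory.times.copy(), vdw=vdw, coulomb=coul)


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto centered
    ``reference`` (determinant +1 enforced by flipping the smallest singular
    direction when needed)."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def rmsd_series(
    trajectory: Trajectory,
    reference: int = 0,
    selection: Selection | None = None,
) -> RmsdSeries:
    """Cα-style RMSD per frame after Kabsch superposition onto ``reference``.

    ``selection`` defaults to all atoms named CA; at least 3 atoms are
    required for the superposition to be well-posed.
    """
    if not (0 <= reference < trajectory.n_frames):
        raise EnergeticsError(f"reference frame {reference} out of range")
    if selection is None:
        from .selection import resolve_selection

        selection = resolve_selection(trajectory.topology, "name == CA")
    idx = selection.indices()
    if len(idx) < 3:
        raise EnergeticsError(
            f"superposition needs >=3 selected atoms, got {len(idx)}"
        )
    ref = trajectory.frames[reference][idx]
    ref_centered = ref - ref.mean(axis=0)
    out = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        mob = trajectory.frames[k][idx]
        mob_centered = mob - mob.mean(axis=0)
        rot = kabsch_rotation(mob_centered, ref_centered)
        aligned = mob_centered @ rot.T
        out[k] = np.sqrt(np.mean(np.sum((aligned - ref_centered) ** 2, axis=1)))
    return RmsdSeries(times=trajectory.times.copy(), rmsd=out)
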