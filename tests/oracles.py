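"""Independent brute-force oracles used to validate the package detectors.

Everything here is deliberately written as naive double/triple loops or
closed forms that share no code with the implementations under test.
"""
from __future__ import annotations

import math

import numpy as np


def brute_contact_count(coords, idx_a, idx_b, cutoff, heavy=None) -> int:
    count = 0
    for a in idx_a:
        if heavy is not None and not heavy[a]:
            continue
        for b in idx_b:
            if heavy is not None and not heavy[b]:
                continue
            d = math.dist(coords[a], coords[b])
            if d <= cutoff:
                count += 1
    return count


def brute_hbonds(coords, donor_h_pairs, acceptors, da_cutoff, angle_min) -> set:
    """donor_h_pairs: iterable of (donor_idx, [h_idx, ...])."""
    found = set()
    for d, hs in donor_h_pairs:
        for a in acceptors:
            if a == d:
                continue
            if math.dist(coords[d], coords[a]) > da_cutoff:
                continue
            for h in hs:
                v1 = np.asarray(coords[d]) - np.asarray(coords[h])
                v2 = np.asarray(coords[a]) - np.asarray(coords[h])
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang >= angle_min:
                    found.add((d, h, a))
                    break
    return found


def brute_salt_bridge_pairs(coords, cation_idx, anion_idx, cutoff) -> dict:
    """Minimum distance per (cation atom, anion atom) pair within cutoff."""
    out = {}
    for c in cation_idx:
        for a in anion_idx:
            d = math.dist(coords[c], coords[a])
            if d <= cutoff:
                out[(c, a)] = d
    return out


def brute_min_distance(coords_a, point) -> float:
    return min(math.dist(p, point) for p in coords_a)


def brute_blocking_onset(flags, persistence=1.0):
    """Scan every candidate onset frame; None when no suffix qualifies."""
    n = len(flags)
    for k in range(n):
        suffix = flags[k:]
        if sum(suffix) / len(suffix) >= persistence:
            return k
    return None


def quaternion_superposition_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion (Horn) method.

    Independent of the Kabsch/SVD route: builds the 4x4 key matrix from the
    correlation tensor and uses its largest eigenvalue.
    """
    p = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    q = np.asarray(reference, float) - np.mean(reference, axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    n = len(p)
    msd = (np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / n
    return math.sqrt(max(0.0, msd))


def armchair_atom_count_from_density(n: int, n_cells: int, cc_bond: float) -> int:
    """Atom count of an armchair tube segment from the honeycomb area density.

    Circumference 3*n*a, length n_cells*sqrt(3)*a, one atom per
    (3*sqrt(3)/4)*a^2 of graphene area.
    """
    area = (3.0 * n * cc_bond) * (n_cells * math.sqrt(3.0) * cc_bond)
    per_atom = (3.0 * math.sqrt(3.0) / 4.0) * cc_bond**2
    return round(area / per_atom)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
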