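"""Shared small-molecule geometry: torsions, NeRF atom placement, Kabsch
superposition and r.m.s.d. helpers."""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates (Engh–Huber-like values)
BOND = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("N", "H"): 1.020,
    ("CA", "CB"): 1.521,
}
ANGLE = {
    ("C", "N", "CA"): 121.7,
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,
    ("CA", "C", "O"): 120.8,
    ("C", "N", "H"): 119.0,
    ("N", "CA", "CB"): 110.4,
}
OMEGA = 180.0  # trans peptide


def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed torsion angle in degrees (IUPAC convention).

    Accepts single points or ``(n, 3)`` stacks.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(-y, x))


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A, B, C with internal coordinates
    |CD| = bond, angle(BCD) = angle, torsion(ABCD) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def wrap_degrees(delta) -> np.ndarray:
    """Wrap an angular difference into (-180, 180]."""
    return -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix mapping centered ``mobile`` onto
    centered ``target`` (proper rotation, no reflection)."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray,
              fit_idx: np.ndarray | None = None) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` using the atoms in
    ``fit_idx`` (all atoms by default); returns transformed copy of the
    full mobile array."""
    if fit_idx is None:
        fit_idx = np.arange(len(mobile))
    mc = mobile[fit_idx].mean(axis=0)
    tc = target[fit_idx].mean(axis=0)
    rot = kabsch_rotation(mobile[fit_idx] - mc, target[fit_idx] - tc)
    return (mobile - mc) @ rot.T + tc


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def aligned_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """r.m.s.d. after optimal rigid superposition of ``a`` onto ``b``."""
    return rmsd(superpose(a, b), b)
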