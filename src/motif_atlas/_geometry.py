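"""Rigid-body helpers shared by base-frame fitting, discrepancy, and fixtures."""

from __future__ import annotations

import numpy as np


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of point set ``P`` onto ``Q``.

    Returns the proper rotation ``R`` and translation ``t`` minimizing
    ``sum_i || R @ P[i] + t - Q[i] ||^2`` (reflections are excluded).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects two equally shaped (n, 3) arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # pragma: no cover - degenerate input
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return R, t


def rotation_angle(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Angle in [0, pi] of the relative rotation taking ``Ra`` to ``Rb``.

    Computed as atan2(sin, cos) of the relative rotation, which stays
    well-conditioned at both ends of the range (arccos alone loses ~8
    digits near zero).
    """
    M = Ra.T @ Rb
    c = (np.trace(M) - 1.0) / 2.0
    s = np.linalg.norm(M - M.T) / (2.0 * np.sqrt(2.0))
    return float(np.arctan2(s, np.clip(c, -1.0, 1.0)))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def small_random_rotation(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Random rotation with angle ~ |N(0, sigma)| about a uniform random axis."""
    if sigma == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-12:  # pragma: no cover
        axis = rng.normal(size=3)
    angle = abs(rng.normal(0.0, sigma))
    return rotation_about_axis(axis, angle)
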