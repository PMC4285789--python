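"""Small 3-D geometry helpers shared across modules.

Everything here operates on plain ``numpy`` arrays (shape ``(3,)`` or
``(n, 3)``) and degrees, matching the conventions used throughout the
package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "angle_between",
    "dihedral",
    "rotation_about_axis",
    "place_atom",
    "kabsch_rotation",
    "screw_parameters",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, in degrees, in [0, 180]."""
    c = np.dot(normalize(u), normalize(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, normalize(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(-y, x)))
    return 180.0 if ang <= -180.0 else ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = normalize(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(a, a)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D from A, B, C by internal coordinates (NeRF).

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``torsion_deg``
    the A-B-C-D dihedral.
    """
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ p_i + t ≈ q_i."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - r @ pc
    return r, t


def screw_parameters(r: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Decompose a rigid transform into its screw axis, twist and rise.

    Returns ``(axis, twist_deg, rise)`` where ``axis`` is the unit rotation
    axis, ``twist_deg`` the rotation angle about it and ``rise`` the
    translation component along the axis.
    """
    w, v = np.linalg.eig(r)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = normalize(np.real(v[:, idx]))
    # orient the axis along the translation (the N→C advance)
    if np.dot(t, axis) < 0:
        axis = -axis
    rise = float(np.dot(t, axis))
    # signed right-handed rotation angle about the oriented axis
    test = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(test, axis)) > 0.9:
        test = np.array([0.0, 1.0, 0.0])
    perp = normalize(test - np.dot(test, axis) * axis)
    rp = r @ perp
    twist = float(
        np.degrees(np.arctan2(np.dot(np.cross(perp, rp), axis), np.dot(perp, rp)))
    )
    return axis, twist, rise
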