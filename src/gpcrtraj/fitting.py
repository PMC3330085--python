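"""Shared rigid-body and small-geometry primitives (Kabsch fit, dihedrals, planes)."""

from __future__ import annotations

import numpy as np

from .exceptions import GeometryError

__all__ = ["kabsch", "apply_fit", "rmsd_after_fit", "dihedral", "plane_normal"]


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t so that R @ mobile + t ~ target.

    Least-squares (Kabsch) superposition; a reflection-degenerate SVD solution is
    corrected to det(R) = +1.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise GeometryError("superposition needs two equal sets of >=3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = tc - rot @ mc
    return rot, trans


def apply_fit(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def rmsd_after_fit(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD of two point sets after optimal superposition."""
    rot, trans = kabsch(mobile, target)
    diff = apply_fit(mobile, rot, trans) - target
    return float(np.sqrt((diff**2).sum() / mobile.shape[0]))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """IUPAC dihedral angle in degrees, in (-180, 180]; cis = 0, right-handed positive."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("degenerate dihedral: coincident central atoms")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >=3 non-collinear points."""
    points = np.asarray(points, float)
    if points.shape[0] < 3:
        raise GeometryError("plane fit needs >=3 points")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:  # all points on a line
        raise GeometryError("plane fit is degenerate: points are collinear")
    return vt[2]
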