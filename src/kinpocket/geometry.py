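"""Small vector-geometry toolkit shared across the annotation modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return np.asarray(v, dtype=float) / n


def perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``v``."""
    v = unit(v)
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return unit(np.cross(v, ref))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in degrees."""
    u1, u2 = unit(np.asarray(a) - b), unit(np.asarray(c) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))))


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a (near-)planar atom cycle via SVD."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def interplane_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two planes in [0, 90] degrees (normal orientation free)."""
    c = abs(float(np.clip(np.dot(unit(n1), unit(n2)), -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def principal_axis(coords: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    """Dominant direction of a point cloud (unit vector).

    The sign is fixed deterministically: positive projection on ``orient``
    when given, else on the first-to-last point vector.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    ref = orient if orient is not None else coords[-1] - coords[0]
    if np.dot(axis, ref) < 0:
        axis = -axis
    return axis


def dihedral_about_axis(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees) between projections of v1, v2 on the plane
    perpendicular to ``axis``."""
    ax = unit(axis)
    p1 = np.asarray(v1, float) - np.dot(v1, ax) * ax
    p2 = np.asarray(v2, float) - np.dot(v2, ax) * ax
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        return 0.0
    p1, p2 = unit(p1), unit(p2)
    cosang = np.clip(np.dot(p1, p2), -1.0, 1.0)
    sinang = np.dot(np.cross(p1, p2), ax)
    return float(np.degrees(np.arctan2(sinang, cosang)))


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid rotation/translation mapping mobile onto target.

    Returns (R, t) with ``x @ R.T + t`` the transformed coordinates and
    det(R) = +1 (proper rotation, reflections excluded).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    return r, t


def apply_rigid(coords: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ r.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must match in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
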