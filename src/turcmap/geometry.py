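"""Rotation algebra, rigid superposition, and line/axis geometry.

Conventions used throughout the package:

* Quaternions are **scalar-first** ``(w, x, y, z)`` unit quaternions.
* A quaternion acts as a local-frame -> world-frame map,
  ``v_world = R(q) @ v_local``, where ``R(q)`` is the standard rotation
  matrix of ``q``.
* The canonical representative of the double cover ``{q, -q}`` has
  ``w >= 0``; for ``w == 0`` the first nonzero vector component is made
  non-negative.
* Angles are exposed in degrees at every public interface; radians are
  used internally.

Lengths are unit-agnostic here (nm in the spatial modules, Angstrom in the
conformation module); a single call never mixes units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "InvalidRotationError",
    "DegenerateGeometryError",
    "RigidTransform",
    "Polyline",
    "Axis",
    "quat_canonicalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "quat_from_matrix",
    "relative_orientation",
    "rotate_vector",
    "quat_angle",
    "quat_mean",
    "random_rotation",
    "kabsch_superpose",
    "point_to_polyline",
    "fit_axis_tls",
]

_UNIT_TOL = 1e-9
_DEGENERACY_RTOL = 1e-6


class InvalidRotationError(ValueError):
    """Raised for zero-norm or otherwise unusable rotation inputs."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric fit is underdetermined (collinear points,
    isotropic clouds, eigenvalue ties)."""


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


def _as_quat(q) -> np.ndarray:
    a = np.asarray(q, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"expected a 4-component quaternion, got shape {a.shape}")
    return a


def quat_canonicalize(q) -> np.ndarray:
    """Normalize a quaternion-like 4-tuple and map it to the canonical
    (w >= 0) representative of its rotation.

    For w == 0 the sign is fixed so that the first nonzero vector
    component is non-negative.
    """
    a = _as_quat(q)
    n = np.linalg.norm(a)
    if n <= 0 or not np.isfinite(n):
        raise InvalidRotationError("zero-norm quaternion does not encode a rotation")
    a = a / n
    if a[0] < 0:
        a = -a
    elif a[0] == 0.0:
        for c in a[1:]:
            if c != 0.0:
                if c < 0:
                    a = -a
                break
    # kill negative zeros for deterministic text output
    return a + 0.0


def quat_multiply(qa, qb) -> np.ndarray:
    """Hamilton product qa (x) qb, so that R(qa (x) qb) = R(qa) @ R(qb)."""
    w1, x1, y1, z1 = _as_quat(qa)
    w2, x2, y2, z2 = _as_quat(qb)
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q) -> np.ndarray:
    a = _as_quat(q)
    return np.array([a[0], -a[1], -a[2], -a[3]])


def quat_to_matrix(q) -> np.ndarray:
    a = _as_quat(q)
    return Rotation.from_quat([a[1], a[2], a[3], a[0]]).as_matrix()


def quat_from_matrix(m) -> np.ndarray:
    x, y, z, w = Rotation.from_matrix(np.asarray(m, dtype=float)).as_quat()
    return quat_canonicalize([w, x, y, z])


def relative_orientation(q_a, q_b) -> np.ndarray:
    """Canonicalized relative rotation q_a^-1 (x) q_b.

    ``relative_orientation(q, q)`` is the identity; composing the result
    back onto ``q_a`` reproduces ``q_b`` up to sign.
    """
    return quat_canonicalize(quat_multiply(quat_conjugate(q_a), q_b))


def rotate_vector(q, v) -> np.ndarray:
    """Apply the rotation of unit quaternion ``q`` to 3-vector ``v``."""
    return quat_to_matrix(q) @ _as_vec3(v)


def quat_angle(q_a, q_b) -> float:
    """Geodesic rotation angle between two unit quaternions, in degrees.

    Antipode-invariant: angle = 2 * arccos(|<q_a, q_b>|), in [0, 180].
    """
    d = abs(float(np.dot(_as_quat(q_a), _as_quat(q_b))))
    d = min(d, 1.0)
    return float(np.degrees(2.0 * np.arccos(d)))


def quat_mean(qs) -> np.ndarray:
    """Average of unit quaternions via the dominant eigenvector of the
    accumulated outer-product matrix.

    Inputs are sign-aligned to the first quaternion so the double cover
    cannot cancel the mean.  An eigenvalue tie signals a direction-free
    set (e.g. antipodal rotations) and raises DegenerateGeometryError.
    """
    arr = [np.asarray(_as_quat(q), dtype=float) for q in qs]
    if len(arr) == 0:
        raise ValueError("quat_mean requires a non-empty list")
    ref = arr[0]
    m = np.zeros((4, 4))
    for q in arr:
        if np.dot(q, ref) < 0:
            q = -q
        m += np.outer(q, q)
    vals, vecs = np.linalg.eigh(m)
    if len(arr) > 1 and (vals[-1] - vals[-2]) <= 1e-9 * max(vals[-1], 1.0):
        raise DegenerateGeometryError("quaternion mean is degenerate (eigenvalue tie)")
    return quat_canonicalize(vecs[:, -1])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (scalar-first unit quaternion)."""
    q = rng.normal(size=4)
    return quat_canonicalize(q)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body map ``p -> R(rotation) @ p + translation``."""

    rotation: np.ndarray  # scalar-first unit quaternion
    translation: np.ndarray  # 3-vector

    def __post_init__(self):
        object.__setattr__(self, "rotation", quat_canonicalize(self.rotation))
        object.__setattr__(self, "translation", _as_vec3(self.translation))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ quat_to_matrix(self.rotation).T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        rinv = quat_conjugate(self.rotation)
        return RigidTransform(rinv, -rotate_vector(rinv, self.translation))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(p) == self.apply(other.apply(p))."""
        return RigidTransform(
            quat_multiply(self.rotation, other.rotation),
            rotate_vector(self.rotation, other.translation) + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3))


@dataclass(frozen=True)
class Polyline:
    """Ordered 3D polyline with cumulative arc length per vertex."""

    vertices: np.ndarray  # (n, 3)
    arc_lengths: np.ndarray = field(init=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise ValueError("a polyline needs >= 2 vertices of dimension 3")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline vertices must be finite")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive polyline vertices must be distinct")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(
            self, "arc_lengths", np.concatenate([[0.0], np.cumsum(seg)])
        )

    @property
    def total_length(self) -> float:
        return float(self.arc_lengths[-1])


@dataclass(frozen=True)
class Axis:
    """Line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = _as_vec3(self.point)
        d = _as_vec3(self.direction)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            if n <= 0:
                raise InvalidRotationError("axis direction must be nonzero")
            d = d / n
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    def radial_axial(self, points):
        """Cylindrical coordinates about the axis: (r >= 0, signed s)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        s = pts @ self.direction
        perp = pts - np.outer(s, self.direction)
        r = np.linalg.norm(perp, axis=1)
        return r, s


def kabsch_superpose(moving, fixed, subset=None):
    """Least-squares proper rigid superposition of ``moving`` onto ``fixed``.

    The rotation/translation minimize the RMSD over ``subset`` (all points
    by default); reflections are corrected to proper rotations.  Returns
    ``(RigidTransform, rmsd)`` with the RMSD computed over the subset only.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 3:
        raise ValueError("moving and fixed must be matching (n, 3) arrays")
    idx = np.arange(len(mov)) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 subset points")
    a = mov[idx]
    b = fix[idx]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    if np.linalg.matrix_rank(a0, tol=1e-9 * max(1.0, np.abs(a0).max())) < 2:
        raise DegenerateGeometryError("subset points are collinear or coincident")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    tf = RigidTransform(quat_from_matrix(r), t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(a) - b) ** 2, axis=1))))
    return tf, rmsd


def point_to_polyline(p, line: Polyline):
    """Minimum distance from a point to a polyline.

    Returns ``(distance, foot_point, arc_coordinate)`` where the arc
    coordinate is the cumulative arc length of the foot point, clamped to
    ``[0, total_length]``.
    """
    pt = _as_vec3(p)
    a = line.vertices[:-1]
    b = line.vertices[1:]
    ab = b - a
    seg_len2 = np.sum(ab**2, axis=1)
    t = np.clip(np.sum((pt - a) * ab, axis=1) / seg_len2, 0.0, 1.0)
    feet = a + t[:, None] * ab
    d = np.linalg.norm(feet - pt, axis=1)
    i = int(np.argmin(d))
    arc = float(line.arc_lengths[i] + t[i] * np.sqrt(seg_len2[i]))
    return float(d[i]), feet[i], arc


def fit_axis_tls(points) -> Axis:
    """Total-least-squares line fit: the axis through the centroid whose
    direction minimizes the sum of squared perpendicular (radial)
    distances, i.e. the dominant scatter direction.

    The direction sign is fixed toward positive z (tie: positive y, then
    positive x).  A cloud whose top two scatter eigenvalues agree within
    1e-6 relative has no unique axis and raises DegenerateGeometryError.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("axis fitting needs >= 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    c = pts - centroid
    scatter = c.T @ c
    vals, vecs = np.linalg.eigh(scatter)
    if vals[-1] <= 0:
        raise DegenerateGeometryError("all points identical; axis undefined")
    if (vals[-1] - vals[-2]) <= _DEGENERACY_RTOL * vals[-1]:
        raise DegenerateGeometryError(
            "isotropic point cloud: top scatter eigenvalues tie, axis ambiguous"
        )
    d = vecs[:, -1]
    for c_idx in (2, 1, 0):
        if abs(d[c_idx]) > 1e-9:
            if d[c_idx] < 0:
                d = -d
            break
    return Axis(centroid, d)
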