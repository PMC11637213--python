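"""Shared geometric primitives for crown/pulp point-cloud registration.

All coordinates are in millimetres; all angles reported by this package are
in degrees. The central currencies are :class:`PointCloud` (an (N, 3) array
of surface samples with optional unit normals) and :class:`RigidTransform`
(a proper rotation plus translation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "OrientedBoundingBox",
    "PcaFrame",
    "DegenerateGeometryError",
    "estimate_normals",
    "compute_obb",
    "apply_transform",
    "knn_search",
    "pca_frame",
]

_UNIT_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when point geometry is too degenerate for the requested op.

    Carries ``indices`` when specific offending points can be named.
    """

    def __init__(self, message: str, indices: Sequence[int] | None = None):
        super().__init__(message)
        self.indices = list(indices) if indices is not None else None


@dataclass
class PointCloud:
    """An ordered set of 3D points (mm) with optional outward unit normals.

    Parameters
    ----------
    points
        (N, 3) float array.
    normals
        Optional (N, 3) float array of unit vectors.
    source_tag
        One of ``{"scan", "cbct_crown", "cbct_pulp", "other"}``; records
        which imaging modality the cloud came from.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    source_tag: str = "other"

    _VALID_TAGS = ("scan", "cbct_crown", "cbct_pulp", "other")

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
                raise ValueError("normals must be unit length (tol 1e-6)")
        if self.source_tag not in self._VALID_TAGS:
            raise ValueError(f"source_tag must be one of {self._VALID_TAGS}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def with_points(self, points: np.ndarray, normals=None) -> "PointCloud":
        return PointCloud(points, normals, self.source_tag)

    def kdtree(self) -> cKDTree:
        return cKDTree(self.points)


@dataclass
class RigidTransform:
    """A proper rigid motion p -> R p + t (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation is not orthogonal (tol 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1 (tol 1e-9)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        axis = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls(_project_so3(R), np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other, i.e. the transform applying ``other`` first."""
        return RigidTransform(
            _project_so3(self.rotation @ other.rotation),
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _project_so3(R: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (guards against accumulated round-off)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass
class OrientedBoundingBox:
    """PCA-oriented bounding box of a point cloud.

    ``center`` is the arithmetic mean of the generating points; ``axes``
    rows are orthonormal principal directions (descending variance);
    ``half_extents`` are chosen so the box about ``center`` contains every
    generating point. Corners are labelled A..D on the top (+axis-3) face
    and A'..D' on the bottom face, a convention used to carve the
    "equivalent crown" cut plane.
    """

    center: np.ndarray
    axes: np.ndarray  # (3, 3), rows are unit axis directions
    half_extents: np.ndarray
    corner_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float)
        self.half_extents = np.asarray(self.half_extents, dtype=float).reshape(3)
        if np.abs(self.axes @ self.axes.T - np.eye(3)).max() > 1e-9:
            raise ValueError("OBB axes must be orthonormal (tol 1e-9)")
        if np.any(self.half_extents <= 0):
            raise ValueError("half extents must be positive")
        if not self.corner_labels:
            self.corner_labels = self._label_corners()

    def _label_corners(self) -> dict:
        a1, a2, a3 = (self.axes[i] * self.half_extents[i] for i in range(3))
        c = self.center
        # Top face (occlusal, +axis3): A, B, C, D counter-clockwise.
        top = {"A": c + a1 + a2 + a3, "B": c - a1 + a2 + a3,
               "C": c - a1 - a2 + a3, "D": c + a1 - a2 + a3}
        bot = {k + "'": v - 2 * a3 for k, v in top.items()}
        return {**top, **bot}

    @property
    def bottom_face(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, occlusally-pointing unit normal) of face A'B'C'D'."""
        return self.center - self.axes[2] * self.half_extents[2], self.axes[2].copy()

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        local = (np.asarray(points) - self.center) @ self.axes.T
        return np.all(np.abs(local) <= self.half_extents + tol, axis=1)


@dataclass
class PcaFrame:
    """Centroid + principal-axis frame of a cloud (right-handed, canonical signs)."""

    origin: np.ndarray
    axes: np.ndarray  # rows, descending variance

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float)
        if np.abs(self.axes @ self.axes.T - np.eye(3)).max() > 1e-8:
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed")

    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix (frame axes as columns)."""
        return self.axes.T


# ---------------------------------------------------------------------------
# operations


def knn_search(target: PointCloud, query, k: int) -> np.ndarray:
    """Indices of the ``k`` nearest target points to ``query``.

    Ascending by distance; exact ties broken by the lower index so results
    are platform-stable.
    """
    n = len(target)
    if n == 0:
        raise ValueError("target cloud is empty")
    if k > n:
        raise ValueError(f"k={k} exceeds cloud size {n}")
    query = np.asarray(query, dtype=float).reshape(3)
    # Over-query a little so boundary ties can be re-ordered by index.
    kk = min(n, k + 8)
    d, idx = target.kdtree().query(query, k=kk)
    d, idx = np.atleast_1d(d), np.atleast_1d(idx)
    order = np.lexsort((idx, d))
    return idx[order][:k]


def apply_transform(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Rigidly move a cloud: points get R p + t, normals get R n."""
    pts = T.apply(cloud.points)
    nrm = None if cloud.normals is None else cloud.normals @ T.rotation.T
    return PointCloud(pts, nrm, cloud.source_tag)


def estimate_normals(cloud: PointCloud, k: int = 12, *, flip: bool = False) -> PointCloud:
    """Per-point unit normals from k-neighborhood PCA.

    Each normal is the smallest-eigenvalue eigenvector of the local
    covariance, oriented away from the cloud centroid (tooth crowns are
    locally convex on the occlusal side); ``flip`` inverts the convention.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if len(cloud) < k + 1:
        raise ValueError("cloud must have at least k+1 points")
    tree = cloud.kdtree()
    _, idx = tree.query(cloud.points, k=k + 1)  # includes the point itself
    neigh = cloud.points[idx]  # (N, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    w, v = np.linalg.eigh(cov)
    degenerate = np.nonzero(w[:, 2] < 1e-18)[0]
    if degenerate.size:
        raise DegenerateGeometryError(
            f"{degenerate.size} points have degenerate (coincident) neighborhoods",
            indices=degenerate,
        )
    normals = v[:, :, 0]  # smallest eigenvalue eigenvector
    outward = cloud.points - cloud.centroid
    signs = np.where(np.einsum("ij,ij->i", normals, outward) < 0, -1.0, 1.0)
    if flip:
        signs = -signs
    normals = normals * signs[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(cloud.points.copy(), normals, cloud.source_tag)


def _canonical_pca_axes(points: np.ndarray, *, require_rank: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Descending-variance orthonormal axes with deterministic signs.

    Sign of axes 1 and 2 chosen so their dot with the matching global axis
    is >= 0; axis 3 completes a right-handed triad.
    """
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if w[require_rank - 1] < max(w[0], 1e-30) * 1e-12:
        raise DegenerateGeometryError(
            "covariance is rank-deficient (collinear/coplanar points)")
    axes = v.T.copy()
    for i in range(2):
        if axes[i, i] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes, w


def compute_obb(cloud: PointCloud) -> OrientedBoundingBox:
    """Oriented bounding box with centroid center and PCA axes."""
    if len(cloud) < 4:
        raise DegenerateGeometryError("need at least 4 points for an OBB")
    axes, _ = _canonical_pca_axes(cloud.points)
    center = cloud.centroid
    local = np.abs((cloud.points - center) @ axes.T)
    half = local.max(axis=0)
    if np.any(half < 1e-12):
        raise DegenerateGeometryError("points are coplanar; OBB extent degenerate")
    return OrientedBoundingBox(center, axes, half)


def pca_frame(cloud: PointCloud) -> PcaFrame:
    """Centroid-origin principal frame (descending variance, canonical signs)."""
    if len(cloud) < 4:
        raise DegenerateGeometryError("need at least 4 points for a PCA frame")
    axes, _ = _canonical_pca_axes(cloud.points, require_rank=2)
    return PcaFrame(cloud.centroid, axes)
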