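"""Pulp-horn mapping-surface registration (PHMSR).

The method registers an intraoral-scan crown cloud (free/source) onto a
CBCT crown cloud (fixed/target) while protecting the pose of the CBCT
pulp, which the scan cannot see. It has three ingredients:

1. **Pulp-horn feature mapping (PHFM).** Each pulp horn (the apical spike
   of the pulp chamber under a cusp) defines a feature direction, the
   unit vector from the pulp centroid to the horn apex. Crown CBCT points
   whose surface normal lies within ``gamma_max`` degrees of some horn
   direction are the *mapping points* — the crown region that most
   constrains the pulp pose.
2. **Mapping surfaces.** Around each mapping point a local quadric
   z' = a0 + a1 x' + a2 y' + a3 x'^2 + a4 x' y' + a5 y'^2 is fitted by
   moving least squares (Gaussian weights, scale r/2) to its
   k_c-neighbourhood and sampled on a grid of span d_s inside a disk of
   radius r_s. Free points whose nearest fixed point lies in (or next to)
   the mapping set are matched to the nearest *surface sample* instead of
   the nearest raw point, turning point-point into point-surface
   correspondences that smooth over CBCT quantisation noise.
3. **Sparse alignment.** The correspondences are solved with an l_p
   (p <= 2, default 0.5) sparse ICP step via ADMM: auxiliary residuals z_h
   carry the l_p penalty, the rigid update is a closed-form weighted
   Procrustes, and Lagrange multipliers tie the two together.

Defaults follow the method's published settings: gamma_max 20 deg and
r = 0.1 mm for small initial deviations, 25 deg and 0.3 mm for large
ones; p = 0.5, mu = 10, n2 = 2 correspondence refreshes per outer
iteration, ns = 3 ADMM passes per refresh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry_core import (DegenerateGeometryError, PointCloud,
                            RigidTransform, estimate_normals, pca_frame)

__all__ = [
    "PulpHornFeature",
    "MappingSelection",
    "LocalSurfacePatch",
    "CorrespondenceSet",
    "SparseIcpState",
    "RegistrationResult",
    "pulp_horn_feature_directions",
    "phfm_select_mapping_points",
    "fit_mls_patch",
    "sample_patch",
    "match_point_to_surface",
    "admm_sparse_solve",
    "admm_objective",
    "lp_alignment_cost",
    "register_phmsr",
    "kabsch",
    "PRESETS",
]

#: preset -> (gamma_max [deg], r_fit = r_sample [mm])
PRESETS = {"small": (20.0, 0.1), "large": (25.0, 0.3)}


@dataclass
class PulpHornFeature:
    """One pulp horn: apex position and its feature direction (unit)."""

    apex: np.ndarray
    direction: np.ndarray
    source: str = "automatic"  # or "manual"

    def __post_init__(self):
        self.apex = np.asarray(self.apex, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("horn direction must be nonzero")
            self.direction = self.direction / n


@dataclass
class MappingSelection:
    """Crown-CBCT indices retained by PHFM at angle threshold gamma_max."""

    indices: np.ndarray
    gamma_max: float

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=int))


@dataclass
class LocalSurfacePatch:
    """MLS quadric patch over a local neighbourhood of the fixed cloud."""

    center_index: int
    fit_radius: float
    quadric_coeffs: np.ndarray | None = None
    frame_origin: np.ndarray | None = None
    frame_axes: np.ndarray | None = None  # rows e1, e2, e3 (e3 = normal)
    sample_radius: float | None = None
    sample_span: float | None = None
    samples: np.ndarray | None = None
    degenerate: bool = False

    def evaluate_local(self, u, v):
        """Quadric height z'(u, v) in the local tangent frame."""
        a = self.quadric_coeffs
        return a[0] + a[1] * u + a[2] * v + a[3] * u * u + a[4] * u * v + a[5] * v * v


@dataclass
class CorrespondenceSet:
    """Matched (target point c'_h, free point y_h) pairs."""

    target_points: np.ndarray
    source_points: np.ndarray
    source_indices: np.ndarray
    surface_mask: np.ndarray | None = None
    weights: np.ndarray | None = None
    mode: str = "point_point"

    def __post_init__(self):
        self.target_points = np.asarray(self.target_points, dtype=float)
        self.source_points = np.asarray(self.source_points, dtype=float)
        if self.target_points.shape != self.source_points.shape:
            raise ValueError("target/source point arrays must match in shape")
        if not np.isfinite(self.target_points).all():
            raise ValueError("target points must be finite")
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        if self.surface_mask is None:
            self.surface_mask = np.zeros(len(self.target_points), dtype=bool)
        if self.weights is None:
            self.weights = np.ones(len(self.target_points))
        else:
            self.weights = np.asarray(self.weights, dtype=float)

    def __len__(self) -> int:
        return len(self.target_points)


@dataclass
class SparseIcpState:
    """ADMM state of the sparse l_p alignment (Z residuals, multipliers)."""

    p: float = 0.5
    mu: float = 10.0
    n2: int = 2
    ns: int = 3
    Z: np.ndarray | None = None
    Lambda: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 < self.p <= 2.0):
            raise ValueError("p must be in (0, 2]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    def reset(self, n: int) -> None:
        self.Z = np.zeros((n, 3))
        self.Lambda = np.zeros((n, 3))


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration: transform + diagnostics."""

    transform: RigidTransform
    converged: bool
    n_iterations: int
    method: str
    history: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pulp-horn features and PHFM selection


def pulp_horn_feature_directions(pulp: PointCloud, occlusal_axis,
                                 n_horns: int = 4,
                                 manual_overrides: Sequence[PulpHornFeature] | None = None,
                                 min_separation_mm: float = 1.0,
                                 ) -> list[PulpHornFeature]:
    """Detect pulp horn apexes and their feature directions.

    Apexes are the ``n_horns`` highest local maxima of the pulp cloud
    along the occlusal axis, laterally separated by at least
    ``min_separation_mm`` (distance in the plane perpendicular to the
    axis, so flank points of an already-claimed horn cannot found a
    second one). The feature direction of a horn is the unit vector from
    the pulp centroid to its apex. ``manual_overrides``, when given, are
    returned verbatim — horn picking is clinically a manual step.
    """
    if manual_overrides is not None:
        return list(manual_overrides)
    if len(pulp) == 0:
        raise ValueError("pulp cloud is empty")
    if n_horns < 1:
        raise ValueError("n_horns must be >= 1")
    axis = np.asarray(occlusal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    heights = pulp.points @ axis
    lateral = pulp.points - np.outer(heights, axis)
    order = np.argsort(heights)[::-1]
    apexes: list[int] = []
    for i in order:
        if all(np.linalg.norm(lateral[i] - lateral[j]) >= min_separation_mm
               for j in apexes):
            apexes.append(i)
            if len(apexes) == n_horns:
                break
    if len(apexes) < n_horns:
        raise ValueError(
            f"found only {len(apexes)} well-separated pulp-horn maxima, "
            f"need {n_horns}")
    centroid = pulp.centroid
    feats = []
    for i in apexes:
        d = pulp.points[i] - centroid
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateGeometryError("horn apex coincides with pulp centroid")
        feats.append(PulpHornFeature(pulp.points[i], d / n, "automatic"))
    return feats


def phfm_select_mapping_points(cbct_crown: PointCloud,
                               horns: Sequence[PulpHornFeature],
                               gamma_max: float) -> MappingSelection:
    """Retain crown points whose normal is within gamma_max of a horn direction.

    The angle to the *best* horn is used: a point is kept iff
    min_h angle(normal, direction_h) <= gamma_max (degrees).
    """
    if cbct_crown.normals is None:
        raise ValueError("cbct_crown must carry normals (run estimate_normals)")
    if not (0.0 <= gamma_max <= 180.0):
        raise ValueError("gamma_max must be within [0, 180] degrees")
    if not horns:
        raise ValueError("at least one pulp horn feature is required")
    D = np.stack([h.direction for h in horns])  # (H, 3)
    cosang = np.clip(cbct_crown.normals @ D.T, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))  # (N, H)
    keep = angles.min(axis=1) <= gamma_max
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise ValueError(
            f"PHFM retained no points at gamma_max={gamma_max} deg; "
            "increase gamma_max")
    return MappingSelection(idx, gamma_max)


# ---------------------------------------------------------------------------
# MLS mapping surfaces


def fit_mls_patch(cbct_crown: PointCloud, center_index: int,
                  fit_radius: float, min_neighbors: int = 24,
                  _tree: cKDTree | None = None) -> LocalSurfacePatch:
    """Fit the local MLS quadric around one fixed-cloud point.

    The ``min_neighbors`` (= k_c) nearest points within ``fit_radius`` of
    the centre form the sample; the tangent frame comes from their PCA
    (normal = smallest-variance direction) and the quadric is fitted by
    weighted least squares with Gaussian weights exp(-d^2/h^2), h =
    fit_radius / 2. Fewer than 6 usable neighbours (the quadric has six
    coefficients) flags the patch degenerate, which downgrades matching
    at this point to plain point-point.
    """
    pts = cbct_crown.points
    c = pts[center_index]
    tree = _tree if _tree is not None else cKDTree(pts)
    k = min(min_neighbors + 1, len(pts))
    d, idx = tree.query(c, k=k)
    d, idx = np.atleast_1d(d), np.atleast_1d(idx)
    inside = d <= fit_radius
    idx, d = idx[inside], d[inside]
    patch = LocalSurfacePatch(center_index=center_index, fit_radius=fit_radius)
    if idx.size < 6:
        patch.degenerate = True
        return patch
    neigh = pts[idx]
    centered = neigh - neigh.mean(axis=0)
    w_eig, v = np.linalg.eigh(centered.T @ centered / len(neigh))
    e3 = v[:, 0]
    e1, e2 = v[:, 2], v[:, 1]
    if np.dot(np.cross(e1, e2), e3) < 0:
        e3 = -e3
    axes = np.stack([e1, e2, e3])
    local = (neigh - c) @ axes.T
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    h = fit_radius / 2.0
    w = np.exp(-(d / h) ** 2)
    A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    sw = np.sqrt(w)
    coeffs, _, rank, _ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
    if rank < 6:
        patch.degenerate = True
        return patch
    patch.quadric_coeffs = coeffs
    patch.frame_origin = c.copy()
    patch.frame_axes = axes
    return patch


def sample_patch(patch: LocalSurfacePatch, sample_radius: float,
                 span: float) -> LocalSurfacePatch:
    """Sample the fitted quadric on a grid of spacing ``span`` in a disk.

    Grid nodes (u, v) with u, v multiples of ``span`` and u^2 + v^2 <=
    sample_radius^2 are lifted onto the quadric and mapped to world
    coordinates. A span exceeding the disk diameter degenerates to the
    single centre sample (with a warning).
    """
    if span <= 0 or sample_radius <= 0:
        raise ValueError("span and sample_radius must be positive")
    if patch.degenerate or patch.quadric_coeffs is None:
        raise ValueError("cannot sample a degenerate/unfitted patch")
    if span > 2.0 * sample_radius:
        warnings.warn("sample span exceeds the patch diameter; returning the "
                      "single centre sample", stacklevel=2)
        uv = np.zeros((1, 2))
    else:
        m = int(np.floor(sample_radius / span))
        ticks = span * np.arange(-m, m + 1)
        U, V = np.meshgrid(ticks, ticks, indexing="ij")
        uv = np.column_stack([U.ravel(), V.ravel()])
        uv = uv[np.einsum("ij,ij->i", uv, uv) <= sample_radius ** 2 + 1e-12]
    z = patch.evaluate_local(uv[:, 0], uv[:, 1])
    local = np.column_stack([uv, z])
    patch.samples = patch.frame_origin + local @ patch.frame_axes
    patch.sample_radius = sample_radius
    patch.sample_span = span
    return patch


def _expanded_mapping_mask(cbct_crown: PointCloud, selection: MappingSelection,
                           k_y: int, tree: cKDTree) -> np.ndarray:
    """Boolean mask of points in the selection or its k_y-neighbourhood."""
    mask = np.zeros(len(cbct_crown), dtype=bool)
    mask[selection.indices] = True
    if k_y > 0 and selection.indices.size:
        k = min(k_y + 1, len(cbct_crown))
        _, idx = tree.query(cbct_crown.points[selection.indices], k=k)
        mask[np.unique(idx)] = True
    return mask


class _SurfaceMatcher:
    """Vectorised point-to-surface correspondence search with patch caching.

    Patches depend only on the fixed cloud and the fitting parameters, so
    each is fitted and sampled at most once per registration.
    """

    def __init__(self, cbct_crown: PointCloud, selection: MappingSelection,
                 k_y: int = 8, k_c: int = 24, r_fit: float = 0.3,
                 r_sample: float = 0.3, d_sample: float | None = None,
                 adaptive_radius: bool = False, mapping_weight: float = 1.0):
        if k_c < 3 * k_y:
            warnings.warn(f"k_c={k_c} violates k_c >= 3*k_y={3 * k_y}; "
                          "matching proceeds but neighbourhoods may be thin",
                          stacklevel=2)
        self.cloud = cbct_crown
        self.tree = cbct_crown.kdtree()
        self.k_c = k_c
        # average span of the target cloud: median NN spacing
        d, _ = self.tree.query(cbct_crown.points, k=2)
        spacing = float(np.median(d[:, 1]))
        if adaptive_radius and spacing > 0:
            # the fitting radius is meaningful only relative to the point
            # spacing; floor it so a quadric spans a few point spacings
            # and stays resolvable on sparse (CBCT-voxel-limited) clouds
            floor = 3.5 * spacing
            r_fit = max(r_fit, floor)
            r_sample = max(r_sample, floor)
        self.r_fit = r_fit
        self.r_sample = r_sample
        if d_sample is None:
            # a few samples per target point spacing keep the patch
            # effectively continuous for the nearest-sample search
            d_sample = spacing / 3.0
            if d_sample <= 0:
                d_sample = max(r_sample / 6.0, 1e-6)
        self.d_sample = d_sample
        self.in_map = _expanded_mapping_mask(cbct_crown, selection, k_y, self.tree)
        self.mapping_weight = float(mapping_weight)
        self._patch_cache: dict[int, np.ndarray | None] = {}

    def patch_samples(self, center_index: int) -> np.ndarray | None:
        if center_index not in self._patch_cache:
            patch = fit_mls_patch(self.cloud, center_index, self.r_fit,
                                  self.k_c, _tree=self.tree)
            if patch.degenerate:
                self._patch_cache[center_index] = None
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sample_patch(patch, self.r_sample, self.d_sample)
                self._patch_cache[center_index] = patch.samples
        return self._patch_cache[center_index]

    def correspondences(self, free_points: np.ndarray) -> CorrespondenceSet:
        free_points = np.asarray(free_points, dtype=float)
        d_raw, nn = self.tree.query(free_points)
        targets = self.cloud.points[nn].copy()
        surf = np.zeros(len(free_points), dtype=bool)
        # a free point that already coincides with a fixed point is a
        # perfect correspondence; replacing it with a patch sample would
        # only inject quadric model error
        candidates = np.nonzero(self.in_map[nn] & (d_raw > 1e-9))[0]
        for c in np.unique(nn[candidates]):
            samples = self.patch_samples(int(c))
            if samples is None:
                continue
            rows = candidates[nn[candidates] == c]
            D = cdist(free_points[rows], samples)
            targets[rows] = samples[np.argmin(D, axis=1)]
            surf[rows] = True
        mode = "point_surface" if surf.any() else "point_point"
        weights = np.where(surf, self.mapping_weight, 1.0)
        return CorrespondenceSet(targets, free_points,
                                 np.arange(len(free_points)), surf, weights,
                                 mode)


def match_point_to_surface(free_point, cbct_crown: PointCloud,
                           selection: MappingSelection, k_y: int = 8,
                           k_c: int = 24, r_fit: float = 0.3,
                           r_sample: float = 0.3,
                           d_sample: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Single-point correspondence (c'_h, y_h) under the mapping-surface rule.

    The nearest fixed point c_h to ``free_point`` is found; if it belongs
    to the mapping selection (or its k_y-neighbourhood) and an MLS patch
    can be fitted there, the nearest patch sample becomes the match c'_h,
    otherwise c_h itself is returned (point-point fallback).
    """
    matcher = _SurfaceMatcher(cbct_crown, selection, k_y, k_c, r_fit,
                              r_sample, d_sample)
    y = np.asarray(free_point, dtype=float).reshape(1, 3)
    corr = matcher.correspondences(y)
    return corr.target_points[0], y[0]


# ---------------------------------------------------------------------------
# sparse l_p ADMM solve


def kabsch(source: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Closed-form weighted Procrustes: min sum w ||R s + t - q||^2."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(source) < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    if weights is None:
        weights = np.ones(len(source))
    wsum = weights.sum()
    ms = (weights[:, None] * source).sum(axis=0) / wsum
    mt = (weights[:, None] * target).sum(axis=0) / wsum
    S = source - ms
    Tt = target - mt
    H = (weights[:, None] * S).T @ Tt
    sv = np.linalg.svd(S, compute_uv=False)
    if sv[1] < max(sv[0], 1e-300) * 1e-9:
        raise DegenerateGeometryError("correspondence geometry is collinear; "
                                      "rotation is not determined")
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mt - R @ ms
    return RigidTransform(R, t)


def _prox_lp_norm(d: np.ndarray, p: float, mu: float,
                  newton_iters: int = 20, tol: float = 1e-10) -> np.ndarray:
    """prox of ||.||_2^p with penalty mu: argmin_z z^p + mu/2 (z - d)^2, z >= 0.

    Vectorised over residual magnitudes ``d``. Closed forms for p = 1, 2;
    a safeguarded Newton solve (20 iterations, tol 1e-10) plus the 0-vs-
    interior objective comparison for fractional p.
    """
    d = np.asarray(d, dtype=float)
    if p == 2.0:
        return d * (mu / (mu + 2.0))
    if p == 1.0:
        return np.maximum(d - 1.0 / mu, 0.0)
    z = d.copy()
    pos = d > 0
    zp = z[pos]
    dp = d[pos]
    for _ in range(newton_iters):
        g = p * zp ** (p - 1.0) + mu * (zp - dp)
        gp = p * (p - 1.0) * zp ** (p - 2.0) + mu
        step = np.where(np.abs(gp) > 1e-300, g / gp, 0.0)
        znew = zp - step
        znew = np.clip(znew, 1e-12 * np.maximum(dp, 1e-12), dp)
        if np.max(np.abs(znew - zp), initial=0.0) < tol:
            zp = znew
            break
        zp = znew
    # keep the interior stationary point only where it beats z = 0
    interior = zp ** p + 0.5 * mu * (zp - dp) ** 2
    at_zero = 0.5 * mu * dp ** 2
    stationary = np.abs(p * zp ** (p - 1.0) + mu * (zp - dp)) < 1e-6 * mu * np.maximum(dp, 1.0)
    zp = np.where(stationary & (interior < at_zero), zp, 0.0)
    z[pos] = zp
    z[~pos] = 0.0
    return z


def admm_objective(corr: CorrespondenceSet, state: SparseIcpState,
                   T: RigidTransform) -> float:
    """Augmented-Lagrangian value at (R, t, Z, Lambda) for fixed pairs.

    Per-pair confidence weights multiply the whole augmented term.
    """
    w = corr.weights
    delta = T.apply(corr.source_points) - corr.target_points - state.Z
    zn = np.linalg.norm(state.Z, axis=1)
    return float((w * zn ** state.p).sum()
                 + np.einsum("i,ij,ij->", w, state.Lambda, delta)
                 + 0.5 * state.mu * np.einsum("i,ij,ij->", w, delta, delta))


def lp_alignment_cost(corr: CorrespondenceSet, T: RigidTransform,
                      p: float) -> float:
    """The sparse alignment objective sum_h w_h ||R y_h + t - c'_h||_2^p."""
    resid = np.linalg.norm(T.apply(corr.source_points) - corr.target_points,
                           axis=1)
    return float((corr.weights * resid ** p).sum())


def admm_sparse_solve(corr: CorrespondenceSet, state: SparseIcpState,
                      initial: RigidTransform | None = None,
                      ) -> tuple[RigidTransform, SparseIcpState]:
    """One sparse l_p alignment solve over fixed correspondences.

    Alternates, for ``state.ns`` passes: (i) z-update via the l_p
    proximal operator on shifted residuals, (ii) rigid update via
    weighted Procrustes on the ADMM-shifted targets, (iii) multiplier
    update Lambda += mu * delta. p = 2 reduces to the plain closed-form
    Procrustes solution (the quadratic case needs no splitting).

    Because the l_p objective is nonconvex for p < 1, each pass carries a
    monotone-descent safeguard: a transform update that would increase
    the alignment cost is rejected (the multiplier update still runs, so
    later passes can escape). The cost sequence is therefore
    non-increasing at fixed correspondences.
    """
    n = len(corr)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    if state.p == 2.0:
        T = kabsch(corr.source_points, corr.target_points, corr.weights)
        state.reset(n)
        resid = T.apply(corr.source_points) - corr.target_points
        state.Z = resid * (state.mu / (state.mu + 2.0))
        state.Lambda = 2.0 * state.Z
        return T, state
    if state.Z is None or len(state.Z) != n:
        state.reset(n)
    T = initial if initial is not None else kabsch(corr.source_points,
                                                  corr.target_points,
                                                  corr.weights)
    mu = state.mu
    cost = lp_alignment_cost(corr, T, state.p)
    for _ in range(state.ns):
        moved = T.apply(corr.source_points)
        resid = moved - corr.target_points
        shifted = resid + state.Lambda / mu
        mags = np.linalg.norm(shifted, axis=1)
        zmag = _prox_lp_norm(mags, state.p, mu)
        scale = np.where(mags > 0, zmag / np.maximum(mags, 1e-300), 0.0)
        state.Z = shifted * scale[:, None]
        # rigid update against the ADMM-shifted targets
        q = corr.target_points + state.Z - state.Lambda / mu
        T_new = kabsch(corr.source_points, q, corr.weights)
        new_cost = lp_alignment_cost(corr, T_new, state.p)
        if new_cost <= cost:
            T, cost = T_new, new_cost
        delta = T.apply(corr.source_points) - corr.target_points - state.Z
        state.Lambda = state.Lambda + mu * delta
    return T, state


# ---------------------------------------------------------------------------
# full PHMSR loop


def register_phmsr(scan_crown: PointCloud, cbct_crown: PointCloud,
                   pulp: PointCloud, deviation_preset: str = "small", *,
                   gamma_max: float | None = None,
                   r_fit: float | None = None,
                   r_sample: float | None = None,
                   d_sample: float | None = None,
                   k_y: int = 16, k_c: int = 48,
                   mapping_weight: float = 3.0,
                   p: float = 0.5, mu: float = 10.0, n2: int = 2, ns: int = 3,
                   n_horns: int = 4,
                   horns: Sequence[PulpHornFeature] | None = None,
                   occlusal_axis=None,
                   normals_k: int = 12,
                   adaptive_radius: bool = True,
                   max_outer: int = 50,
                   rot_tol_deg: float = 0.01,
                   trans_tol_mm: float = 1e-3) -> RegistrationResult:
    """Register the scan crown onto the CBCT crown via mapping surfaces.

    Pipeline: estimate CBCT crown normals -> pulp-horn feature directions
    -> PHFM mapping-point selection -> outer loop of {point-surface
    correspondence search, sparse l_p ADMM solve (n2 refreshes x ns
    passes), incremental transform} until the outer increment falls below
    ``rot_tol_deg`` / ``trans_tol_mm`` or ``max_outer`` iterations.

    Presets resolve the published settings: "small" -> (20 deg, 0.1 mm),
    "large" -> (25 deg, 0.3 mm); explicit keyword values win.
    """
    if deviation_preset not in PRESETS:
        raise ValueError(f"unknown deviation preset {deviation_preset!r}")
    g_preset, r_preset = PRESETS[deviation_preset]
    gamma_max = g_preset if gamma_max is None else gamma_max
    r_fit = r_preset if r_fit is None else r_fit
    r_sample = r_fit if r_sample is None else r_sample

    fixed = cbct_crown
    if fixed.normals is None:
        fixed = estimate_normals(fixed, k=normals_k)
    if occlusal_axis is None:
        occlusal_axis = pca_frame(fixed).axes[2]
    if horns is None:
        horns = pulp_horn_feature_directions(pulp, occlusal_axis, n_horns)
    selection = phfm_select_mapping_points(fixed, horns, gamma_max)
    matcher = _SurfaceMatcher(fixed, selection, k_y, k_c, r_fit, r_sample,
                              d_sample, adaptive_radius=adaptive_radius,
                              mapping_weight=mapping_weight)

    state = SparseIcpState(p=p, mu=mu, n2=n2, ns=ns)
    T = RigidTransform.identity()
    pts = scan_crown.points.copy()
    centroid = scan_crown.centroid
    history: list[dict] = []
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        T_start = T
        corr = None
        for _ in range(n2):
            # "intermediate point" refresh: re-match against the patch
            # samples after every ADMM solve
            corr = matcher.correspondences(pts)
            state.reset(len(corr))
            T_inc, state = admm_sparse_solve(corr, state)
            T = T_inc.compose(T)
            pts = T_inc.apply(pts)
        delta = T.compose(T_start.inverse())
        rot_inc = delta.rotation_angle_deg()
        trans_inc = float(np.linalg.norm(delta.apply(centroid) - centroid))
        resid = np.linalg.norm(corr.target_points - pts[corr.source_indices],
                               axis=1)
        history.append({
            "iteration": n_outer,
            "rms_residual_mm": float(np.sqrt(np.mean(resid ** 2))),
            "rotation_increment_deg": rot_inc,
            "translation_increment_mm": trans_inc,
            "n_surface_pairs": int(corr.surface_mask.sum()),
        })
        if rot_inc < rot_tol_deg and trans_inc < trans_tol_mm:
            converged = True
            break
    return RegistrationResult(
        transform=T,
        converged=converged,
        n_iterations=n_outer,
        method="phmsr",
        history=history,
        metrics={"gamma_max": gamma_max, "r_fit": matcher.r_fit,
                 "r_sample": matcher.r_sample, "d_sample": matcher.d_sample,
                 "n_mapping_points": int(selection.indices.size)},
    )
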