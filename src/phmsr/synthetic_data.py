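"""Synthetic tooth phantoms and degraded clouds for end-to-end testing.

A phantom molar crown is an ellipsoid-like closed surface with Gaussian
cusp bumps on its occlusal face; its pulp is a scaled-down inner surface
with one sharp conical horn under each cusp. From a phantom we derive

* a *scan-like* cloud: dense, crown-only, with tiny surface noise
  (default sigma 0.02 mm, matching intraoral-scanner accuracy of 20 um);
* a *CBCT-like* crown + pulp cloud pair: the meshes are voxelised at the
  CBCT voxel pitch (default 0.25 mm), re-extracted by marching cubes
  (quantisation roughness), and optionally degraded with Gaussian noise,
  gross outliers (1-5 mm displacements) and contiguous occlusal dropout;
* seeded rigid pose perturbations with "small" (<= 5 deg, <= 1 mm) and
  "large" (<= 25 deg, <= 5 mm) presets, returning the exact ground-truth
  transform for recovery tests;
* a segmentation phantom volume (capped-cylinder teeth with an interior
  pulp cavity) with paired ground-truth labels.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .geometry_core import PointCloud, RigidTransform
from .volume_preprocess import LabelVolume, VolumeImage

__all__ = [
    "ToothPhantom",
    "PerturbationPreset",
    "PERTURBATION_PRESETS",
    "make_tooth_phantom",
    "make_scan_cloud",
    "make_cbct_cloud",
    "perturb_pose",
    "make_segmentation_phantom_volume",
]


@dataclass
class PerturbationPreset:
    name: str
    rotation_range_deg: float
    translation_range_mm: float


PERTURBATION_PRESETS = {
    "small": PerturbationPreset("small", 5.0, 1.0),
    "large": PerturbationPreset("large", 25.0, 5.0),
}


@dataclass
class ToothPhantom:
    """Crown + pulp meshes with ground-truth horn/cusp apexes (mm)."""

    crown_mesh: trimesh.Trimesh
    pulp_mesh: trimesh.Trimesh
    horn_apexes: np.ndarray
    cusp_apexes: np.ndarray
    occlusal_axis: np.ndarray
    margin_z: float
    seed: int


def _ellipsoid_mesh(a: float, b: float, c: float, subdivisions: int) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = m.vertices.copy()
    v[:, 0] *= a
    v[:, 1] *= b
    v[:, 2] *= c
    return trimesh.Trimesh(v, m.faces.copy(), process=False)


def make_tooth_phantom(n_cusps: int = 4, crown_diameter_mm: float = 10.0,
                       seed: int = 0, subdivisions: int = 4) -> ToothPhantom:
    """Deterministic molar-like phantom: bumpy crown + horned pulp.

    Cusps sit on a ring at 45% of the crown radius (a single cusp sits on
    the axis) with a small seeded angular jitter; each pulp horn is a
    sharp Gaussian spike under its cusp, placed at 60% of the cusp's
    lateral position. Raises if the pulp would pierce the crown.
    """
    if n_cusps < 1:
        raise ValueError("n_cusps must be >= 1")
    if crown_diameter_mm <= 0:
        raise ValueError("crown diameter must be positive")
    rng = np.random.default_rng(seed)
    d = crown_diameter_mm
    # molar crowns are wider mesiodistally than buccolingually and their
    # cusps differ in height; without that asymmetry the azimuthal pose
    # of the phantom would be nearly unidentifiable
    a, b = 0.50 * d, 0.42 * d
    c = 0.35 * d
    bump_amp, bump_sigma = 0.12 * d, 0.14 * d
    horn_amp, horn_sigma = 0.18 * d, 0.06 * d
    pulp_scale = 0.45

    base_angle = rng.uniform(0, 2 * np.pi)
    if n_cusps == 1:
        centers = np.zeros((1, 2))
        amps = np.array([bump_amp])
    else:
        theta = (2.0 * np.pi * np.arange(n_cusps) / n_cusps
                 + np.deg2rad(rng.uniform(-8.0, 8.0, n_cusps))
                 + base_angle)
        rho = 0.45 * np.sqrt(a * b) * rng.uniform(0.9, 1.1, n_cusps)
        centers = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
        amps = bump_amp * rng.uniform(0.8, 1.2, n_cusps)

    crown = _ellipsoid_mesh(a, b, c, subdivisions)
    v = crown.vertices.copy()
    # smooth occlusal ramp: displacing only z > 0 with a hard cutoff folds
    # triangles on the near-vertical walls and inverts their normals
    occl = np.clip(v[:, 2] / (0.25 * c), 0.0, 1.0)
    for (cx, cy), amp in zip(centers, amps):
        r2 = (v[:, 0] - cx) ** 2 + (v[:, 1] - cy) ** 2
        v[:, 2] += occl * amp * np.exp(-r2 / (2 * bump_sigma ** 2))
    if n_cusps > 1:
        # occlusal fissures along the inter-cusp bisectors: the grooves of
        # a real molar's occlusal table, which anchor the azimuthal pose
        groove_depth, groove_w = 0.06 * d, 0.035 * d
        for ang in (base_angle + np.pi / 4, base_angle + 3 * np.pi / 4):
            nvec = np.array([-np.sin(ang), np.cos(ang)])
            dist = v[:, 0] * nvec[0] + v[:, 1] * nvec[1]
            v[:, 2] -= (occl * groove_depth
                        * np.exp(-dist ** 2 / (2 * groove_w ** 2)))
    crown = trimesh.Trimesh(v, crown.faces.copy(), process=False)
    cusp_apexes = []
    for (cx, cy), amp in zip(centers, amps):
        zc = c * np.sqrt(max(1 - (cx / a) ** 2 - (cy / b) ** 2, 0.0)) + amp
        cusp_apexes.append((cx, cy, zc))
    cusp_apexes = np.asarray(cusp_apexes)

    ap, bp, cp = pulp_scale * a, pulp_scale * b, pulp_scale * c
    pulp = _ellipsoid_mesh(ap, bp, cp, subdivisions)
    pv = pulp.vertices.copy()
    horn_centers = 0.6 * centers
    occl_p = np.clip(pv[:, 2] / (0.25 * cp), 0.0, 1.0)
    for hx, hy in horn_centers:
        r2 = (pv[:, 0] - hx) ** 2 + (pv[:, 1] - hy) ** 2
        pv[:, 2] += occl_p * horn_amp * np.exp(-r2 / (2 * horn_sigma ** 2))
    pulp = trimesh.Trimesh(pv, pulp.faces.copy(), process=False)
    horn_apexes = []
    for hx, hy in horn_centers:
        r2 = (pv[:, 0] - hx) ** 2 + (pv[:, 1] - hy) ** 2
        cand = np.nonzero(r2 < (2 * horn_sigma) ** 2)[0]
        if cand.size == 0:
            cand = np.array([np.argmin(r2)])
        apex = pv[cand[np.argmax(pv[cand, 2])]]
        horn_apexes.append(apex)
    horn_apexes = np.asarray(horn_apexes)

    # pulp must stay strictly inside the crown with real clearance:
    # signed distance of every pulp vertex to the crown surface < -0.2 mm
    from scipy.spatial import cKDTree
    check_rng = np.random.default_rng(phantom_check_seed := seed + 2 ** 20)
    ref, ref_n = _sample_mesh(crown, 30_000, check_rng)
    _, nn = cKDTree(ref).query(pv)
    signed = np.einsum("ij,ij->i", pv - ref[nn], ref_n[nn])
    if signed.max() > -0.01 * d:
        raise ValueError("infeasible phantom geometry: pulp would reach the crown")

    return ToothPhantom(
        crown_mesh=crown,
        pulp_mesh=pulp,
        horn_apexes=horn_apexes,
        cusp_apexes=cusp_apexes,
        occlusal_axis=np.array([0.0, 0.0, 1.0]),
        margin_z=-0.25 * c,
        seed=seed,
    )


def _sample_mesh(mesh: trimesh.Trimesh, count: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted surface samples + their face normals."""
    face_areas = mesh.area_faces
    probs = face_areas / face_areas.sum()
    faces = rng.choice(len(probs), size=count, p=probs)
    r1, r2 = rng.random(count), rng.random(count)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    tri = mesh.triangles[faces]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (tri[:, 2] - tri[:, 0])
    normals = mesh.face_normals[faces]
    return pts, normals


def make_scan_cloud(phantom: ToothPhantom, density_per_mm2: float = 25.0,
                    noise_sigma_mm: float = 0.02, seed: int = 0) -> PointCloud:
    """Dense, low-noise crown-only cloud emulating an intraoral scan.

    Samples the crown surface above the gingival-margin plane at
    ``density_per_mm2`` and jitters each point along its surface normal
    with Gaussian sigma ``noise_sigma_mm`` (default 0.02 mm = the 20 um
    scanner accuracy class).
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    mesh = phantom.crown_mesh
    count = max(int(np.ceil(density_per_mm2 * mesh.area)), 16)
    pts, normals = _sample_mesh(mesh, int(1.8 * count), rng)
    keep = pts[:, 2] >= phantom.margin_z
    pts, normals = pts[keep][:count], normals[keep][:count]
    if noise_sigma_mm > 0:
        pts = pts + normals * rng.normal(0.0, noise_sigma_mm, len(pts))[:, None]
    return PointCloud(pts, None, "scan")


def _voxelized_surface(mesh: trimesh.Trimesh, pitch: float, rng,
                       margin_z: float | None = None,
                       smoothing_iters: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Voxelise a closed mesh at ``pitch`` and re-extract by marching cubes.

    Emulates the CBCT reconstruction chain: voxel occupancy, a 0.5
    marching-cubes isosurface, and Laplacian smoothing of the extracted
    mesh (as applied to clinical CBCT reconstructions before they are
    turned into point clouds); the smoothed vertices with their normals
    become the cloud.
    """
    lo = mesh.bounds[0] - 3 * pitch
    hi = mesh.bounds[1] + 3 * pitch
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    n_dense = max(int(mesh.area / (pitch / 3.0) ** 2), 1000)
    pts, nrm = _sample_mesh(mesh, n_dense, rng)
    # occupancy = voxel centre inside the closed surface, decided by the
    # outward normal of the nearest surface sample; this keeps the
    # marching-cubes interface unbiased (within half a voxel of truth)
    from scipy.spatial import cKDTree
    grids = [lo[i] + (np.arange(shape[i]) + 0.5) * pitch for i in range(3)]
    centres = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    _, nn = cKDTree(pts).query(centres)
    inside = np.einsum("ij,ij->i", centres - pts[nn], nrm[nn]) < 0.0
    solid = inside.reshape(shape)
    verts, faces, _, _ = marching_cubes(solid.astype(float), level=0.5)
    verts = verts * pitch + lo + 0.5 * pitch  # voxel centres -> mm
    if smoothing_iters > 0:
        # shrink-free Taubin variant: a positive and a compensating
        # negative Laplacian step per iteration
        from .volume_preprocess import _laplacian_smooth
        for _ in range(smoothing_iters):
            verts = _laplacian_smooth(verts, faces, 1, lam=0.5)
            verts = _laplacian_smooth(verts, faces, 1, lam=-0.53)
    m = trimesh.Trimesh(verts, faces, process=False)
    normals = np.asarray(m.vertex_normals, dtype=float).copy()
    bad = np.linalg.norm(normals, axis=1) < 1e-12
    normals[bad] = (0.0, 0.0, 1.0)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    outward = verts - verts.mean(axis=0)
    if np.sum(np.einsum("ij,ij->i", normals, outward) < 0) > len(verts) / 2:
        normals = -normals
    if margin_z is not None:
        keep = verts[:, 2] >= margin_z
        verts, normals = verts[keep], normals[keep]
    return verts, normals


def make_cbct_cloud(phantom: ToothPhantom, voxel_mm: float = 0.25,
                    noise_sigma_mm: float = 0.05, outlier_frac: float = 0.0,
                    dropout_frac: float = 0.0, seed: int = 0,
                    smoothing_iters: int = 10) -> tuple[PointCloud, PointCloud]:
    """CBCT-like (crown, pulp) cloud pair in a common frame.

    The crown and pulp surfaces are voxelised at ``voxel_mm`` and
    re-extracted (quantisation roughness), then Gaussian noise of sigma
    ``noise_sigma_mm`` is added along the normals; ``outlier_frac`` of
    the crown points are displaced 1-5 mm along their outward normal and
    ``dropout_frac`` are removed in contiguous occlusal blotches. The
    pulp cloud gets quantisation + noise only and is rigidly consistent
    with the crown.
    """
    for f in (outlier_frac, dropout_frac):
        if not (0.0 <= f < 1.0):
            raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pts, normals = _voxelized_surface(phantom.crown_mesh, voxel_mm, rng,
                                      margin_z=phantom.margin_z,
                                      smoothing_iters=smoothing_iters)
    if noise_sigma_mm > 0:
        pts = pts + normals * rng.normal(0.0, noise_sigma_mm, len(pts))[:, None]
    if dropout_frac > 0:
        target = int(dropout_frac * len(pts))
        removed = np.zeros(len(pts), dtype=bool)
        occl = pts[:, 2] > np.median(pts[:, 2])
        while removed.sum() < target:
            pool = np.nonzero(occl & ~removed)[0]
            if pool.size == 0:
                pool = np.nonzero(~removed)[0]
            centre = pts[rng.choice(pool)]
            blotch = np.linalg.norm(pts - centre, axis=1) < 0.8
            removed |= blotch
        keep = ~removed
        pts, normals = pts[keep], normals[keep]
    if outlier_frac > 0:
        k = int(np.floor(outlier_frac * len(pts)))
        out_idx = rng.choice(len(pts), size=k, replace=False)
        mags = rng.uniform(1.0, 5.0, k)
        pts = pts.copy()
        displaced = pts[out_idx] + normals[out_idx] * mags[:, None]
        # a displacement along a tilted cusp/groove normal can graze the
        # surface; push such points further out so every outlier really
        # is more than 1 mm off the crown
        from scipy.spatial import cKDTree
        ref, _ = _sample_mesh(phantom.crown_mesh, 150_000, rng)
        tree = cKDTree(ref)
        for _ in range(10):
            d, _ = tree.query(displaced)
            close = d < 1.05
            if not close.any():
                break
            displaced[close] += normals[out_idx][close] * 0.5
        pts[out_idx] = displaced
    crown = PointCloud(pts, normals, "cbct_crown")

    ppts, pnormals = _voxelized_surface(phantom.pulp_mesh, voxel_mm, rng,
                                        smoothing_iters=smoothing_iters)
    if noise_sigma_mm > 0:
        ppts = ppts + pnormals * rng.normal(0.0, noise_sigma_mm, len(ppts))[:, None]
    pulp = PointCloud(ppts, pnormals, "cbct_pulp")
    return crown, pulp


def perturb_pose(cloud: PointCloud, preset="small", seed: int = 0,
                 ) -> tuple[PointCloud, RigidTransform]:
    """Apply a seeded random rigid perturbation about the cloud centroid.

    ``preset`` is "small" / "large", a :class:`PerturbationPreset`, or an
    explicit ``(angle_deg, translation_mm)`` pair of range maxima. The
    returned transform is exactly the one applied, so its inverse
    restores the cloud bit-exactly up to floating point.
    """
    if isinstance(preset, str):
        preset = PERTURBATION_PRESETS[preset]
    if isinstance(preset, PerturbationPreset):
        rot_range, trans_range = preset.rotation_range_deg, preset.translation_range_mm
    else:
        rot_range, trans_range = preset
    if rot_range < 0 or trans_range < 0:
        raise ValueError("perturbation ranges must be non-negative")
    rng = np.random.default_rng(seed)
    if rot_range == 0 and trans_range == 0:
        return cloud, RigidTransform.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, rot_range)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    t = tdir * rng.uniform(0.0, trans_range)
    c = cloud.centroid
    rot = RigidTransform.from_axis_angle(axis, angle)
    # rotate about the centroid, then translate
    T = RigidTransform(rot.rotation, c - rot.rotation @ c + t)
    from .geometry_core import apply_transform
    return apply_transform(cloud, T), T


def make_segmentation_phantom_volume(shape=(48, 88, 88), spacing: float = 0.25,
                                     intensities=None, noise_sigma: float = 5.0,
                                     seed: int = 0, n_teeth: int = 1,
                                     ) -> tuple[VolumeImage, LabelVolume]:
    """Capped-cylinder tooth phantom volume with an interior pulp cavity.

    The tooth is a cylinder (axis z, radius 28% of the narrower lateral
    field, height 75% of the axial field) containing an ellipsoidal pulp
    cavity of 45% / 55% of the tooth's radius / half-height;
    ``intensities`` maps class names to grey values (defaults
    background 50 / pulp 100 / tooth 150, a 50-intensity contrast).
    Returns the noisy volume and the exact generating labels
    (0 background, 2.. tooth, then pulp labels).
    """
    if intensities is None:
        intensities = {"background": 50.0, "pulp": 100.0, "tooth": 150.0}
    if len(intensities) < 2:
        raise ValueError("need at least 2 intensity classes")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                          indexing="ij")
    zmm, ymm, xmm = ((g + 0.5) * spacing for g in (z, y, x))
    cz = nz * spacing / 2.0
    height = 0.75 * nz * spacing
    lateral = min(ny, nx) * spacing
    radius = 0.28 * lateral / (1.0 if n_teeth == 1 else 1.6)
    labels = np.zeros(shape, dtype=int)
    legend = {0: "background"}
    if n_teeth == 1:
        centres = [(ny * spacing / 2.0, nx * spacing / 2.0)]
    else:
        gap = nx * spacing / (n_teeth + 1)
        centres = [(ny * spacing / 2.0, gap * (i + 1)) for i in range(n_teeth)]
    lab = 2
    pulp_masks = []
    for cy, cx in centres:
        r2 = (ymm - cy) ** 2 + (xmm - cx) ** 2
        tooth = (r2 <= radius ** 2) & (np.abs(zmm - cz) <= height / 2.0)
        pr, ph = 0.45 * radius, 0.55 * height / 2.0
        pulp = (((ymm - cy) / pr) ** 2 + ((xmm - cx) / pr) ** 2
                + ((zmm - cz) / ph) ** 2) <= 1.0
        labels[tooth & ~pulp] = lab
        legend[lab] = "tooth"
        lab += 1
        pulp_masks.append(pulp)
    for pulp in pulp_masks:
        labels[pulp] = lab
        legend[lab] = "pulp"
        lab += 1
    vox = np.full(shape, float(intensities.get("background", 0.0)))
    for label_id, name in legend.items():
        if label_id == 0:
            continue
        vox[labels == label_id] = float(intensities[name])
    if noise_sigma > 0:
        vox = vox + rng.normal(0.0, noise_sigma, shape)
    return (VolumeImage(vox, spacing),
            LabelVolume(labels, legend, spacing))
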