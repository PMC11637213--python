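"""CBCT volume preprocessing: denoising, SCM segmentation, surface clouds.

The pipeline mirrors how a CBCT scan is turned into registration-ready
point clouds: a wavelet + non-local-means hybrid filter cleans each axial
slice, a spiking cortical model (SCM) with image-adaptive parameters
groups pixels into intensity-synchronous regions, regions are fused across
slices into 3D tooth/pulp structures, and marching cubes plus Laplacian
smoothing turns the chosen structure into a surface point cloud in mm.

The SCM is a simplified pulse-coupled neural network: each pixel is a
neuron with internal activity U driven by its intensity S and by pulses Y
of its neighbours (coupling strength beta, kernel W), firing when U
exceeds a decaying dynamic threshold E. Pixels of similar intensity fire
in the same iteration, so the first-firing time is a contrast-adaptive
quantisation of the image. The five adaptive parameters are derived from
slice statistics:

    alpha_e = C / mean(I)        threshold decay rate
    V_E     = 2 * mean(I)        threshold recharge after firing
    beta    = a * ln(mean(I))    coupling strength (Weber-Fechner)
    alpha_u = ln(1 / var(I))     activity decay rate
    E(0)    = max(I)             initial threshold

``C`` and ``a`` are experimental constants; defaults here keep alpha_e
and beta in the stable range for 8-bit-scaled slices. Note alpha_u is
negative whenever var(I) > 1, which would make the activity recurrence
divergent; the recurrence therefore clips the memory factor
exp(-alpha_u) into [0, 0.25] (see ScmParams.memory_factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
import trimesh
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.measure import marching_cubes
from skimage.restoration import denoise_nl_means

from .geometry_core import PointCloud

__all__ = [
    "VolumeImage",
    "ScmParams",
    "LabelVolume",
    "hybrid_filter",
    "scm_adaptive_params",
    "scm_segment_slice",
    "segment_tooth_and_pulp",
    "extract_surface_cloud",
]


@dataclass
class VolumeImage:
    """3D scalar intensity grid with voxel spacing in mm (index order z,y,x)."""

    voxels: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxel intensities must be finite")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")


@dataclass
class ScmParams:
    """Parameters of one SCM run (see module docstring for the recurrence)."""

    alpha_e: float
    V_E: float
    beta: float
    alpha_u: float
    E0: float
    C: float
    a: float
    W: np.ndarray = field(default_factory=lambda: _default_kernel())
    V_L: float = 1.0
    n_iter: int = 40

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1] or self.W.shape[0] % 2 == 0:
            raise ValueError("W must be a square odd-sided kernel")
        if self.alpha_e <= 0 or self.V_E <= 0:
            raise ValueError("alpha_e and V_E must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def memory_factor(self) -> float:
        """exp(-alpha_u), clipped into [0, 0.25].

        The clip keeps the recurrence stable (alpha_u < 0 whenever
        var(I) > 1, e.g. on any 8-bit slice) and keeps the internal
        activity close to the instantaneous excitation, which preserves
        the log-intensity to firing-time mapping that the segmentation
        relies on.
        """
        return float(np.clip(np.exp(-self.alpha_u), 0.0, 0.25))


def _default_kernel() -> np.ndarray:
    """3x3 inverse-distance coupling weights, zero centre, unit sum.

    Normalising keeps the coupling boost bounded by beta itself, so a
    synchronisation wave cannot jump an intensity-class boundary.
    """
    W = np.array([[1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
                  [1.0, 0.0, 1.0],
                  [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)]])
    return W / W.sum()


@dataclass
class LabelVolume:
    """Integer label grid with a legend mapping labels to structure names."""

    labels: np.ndarray
    legend: dict
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend does not cover labels {sorted(missing)}")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()

    def labels_for(self, name: str) -> list[int]:
        return [lab for lab, n in self.legend.items() if n == name]

    def mask_for(self, which) -> np.ndarray:
        if isinstance(which, str):
            labs = self.labels_for(which)
            if not labs:
                raise KeyError(f"no label named {which!r} in legend")
        else:
            labs = [int(which)]
            if labs[0] not in self.legend:
                raise KeyError(f"label {which} not present")
        return np.isin(self.labels, labs)


# ---------------------------------------------------------------------------
# hybrid wavelet + NL-means filter


def _wavelet_shrink(img: np.ndarray, levels: int) -> np.ndarray:
    coeffs = pywt.wavedec2(img, "sym4", level=levels, mode="symmetric")
    detail = coeffs[-1][-1]
    sigma = np.median(np.abs(detail)) / 0.6745
    if sigma == 0:
        return img.copy()
    thresh = sigma * np.sqrt(2.0 * np.log(img.size))
    shrunk = [coeffs[0]]
    for level in coeffs[1:]:
        shrunk.append(tuple(pywt.threshold(d, thresh, mode="soft") for d in level))
    out = pywt.waverec2(shrunk, "sym4", mode="symmetric")
    return out[: img.shape[0], : img.shape[1]]


def hybrid_filter(vol: VolumeImage, block: int = 2, window: int = 5,
                  decay: float = 10.0, wavelet_levels: int = 2) -> VolumeImage:
    """Per-slice wavelet shrinkage followed by non-local means.

    ``block`` is the NL-means patch size, ``window`` the (odd) search
    window width and ``decay`` the filtering strength h. Defaults are the
    standard CBCT settings (2 / 5 / 10). Output intensities never leave
    the input's [min, max] range.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if window <= block:
        raise ValueError("window must exceed block")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if min(vol.voxels.shape[1:]) < window:
        raise ValueError("volume slices are thinner than the search window")
    lo, hi = float(vol.voxels.min()), float(vol.voxels.max())
    out = np.empty_like(vol.voxels)
    patch_distance = (window - 1) // 2
    for i, sl in enumerate(vol.voxels):
        sm = _wavelet_shrink(sl, wavelet_levels)
        sm = denoise_nl_means(sm, patch_size=block, patch_distance=patch_distance,
                              h=decay, preserve_range=True, fast_mode=True)
        out[i] = sm
    np.clip(out, lo, hi, out=out)
    return VolumeImage(out, vol.spacing)


# ---------------------------------------------------------------------------
# adaptive SCM


def scm_adaptive_params(slice_: np.ndarray, C: float | None = None,
                        a: float = 0.2, n_iter: int = 40) -> ScmParams:
    """Slice-adaptive SCM parameters from image moments.

    ``C`` defaults to 0.02 * max(I): the threshold then decays by a
    factor e every mean/(0.02*max) iterations, which resolves a 2:1
    intensity ratio into >= 5 firing-time bins even on slices dominated
    by dark background (a larger C merges adjacent tissue classes).
    Raises on constant or non-positive-mean slices (alpha_u resp. beta
    undefined).
    """
    I = np.asarray(slice_, dtype=float)
    if I.size == 0:
        raise ValueError("slice is empty")
    mu = float(I.mean())
    var = float(I.var())
    if mu <= 0:
        raise ValueError("slice mean must be positive")
    if var == 0:
        raise ValueError("slice variance is zero; SCM parameters undefined")
    if C is None:
        C = 0.02 * float(I.max())
    return ScmParams(
        alpha_e=C / mu,
        V_E=2.0 * mu,
        beta=a * np.log(mu),
        alpha_u=float(np.log(1.0 / var)),
        E0=float(I.max()),
        C=float(C),
        a=float(a),
        n_iter=n_iter,
    )


def scm_segment_slice(slice_: np.ndarray, params: ScmParams) -> tuple[np.ndarray, np.ndarray]:
    """Run the SCM recurrence; label pixels by first-firing iteration.

    Returns ``(labels, first_fire)``. Pixels that first fire at the same
    iteration share one label; labels are compacted in firing order
    (label 1 fires first, i.e. brightest). Never-fired pixels get label 0
    (background); if more than half the image never fires a warning is
    emitted.
    """
    S = np.asarray(slice_, dtype=float)
    f_u = params.memory_factor
    g_e = float(np.exp(-params.alpha_e))
    U = np.zeros_like(S)
    E = np.full_like(S, params.E0)
    Y = np.zeros_like(S)
    first = np.full(S.shape, -1, dtype=int)
    for n in range(1, params.n_iter + 1):
        L = ndimage.convolve(Y, params.W, mode="constant", cval=0.0)
        U = f_u * U + S * (1.0 + params.beta * params.V_L * L)
        Y = (U > E).astype(float)
        newly = (Y > 0) & (first < 0)
        first[newly] = n
        E = g_e * E + params.V_E * Y
    unfired = first < 0
    if unfired.mean() > 0.5:
        warnings.warn("SCM: more than half of the pixels never fired; "
                      "labelled as background", stacklevel=2)
    labels = np.zeros(S.shape, dtype=int)
    fired_times = np.unique(first[~unfired])
    for lab, t in enumerate(fired_times, start=1):
        labels[first == t] = lab
    return labels, first


def segment_tooth_and_pulp(vol: VolumeImage, C: float | None = None,
                           a: float = 0.2, n_iter: int = 40,
                           min_component_voxels: int = 60,
                           max_teeth: int = 2) -> LabelVolume:
    """Slice-wise adaptive SCM segmentation fused into 3D tooth + pulp labels.

    Each axial slice (rescaled to an 8-bit range so the adaptive formulas
    operate in their stable regime) is segmented by the SCM; per-region
    mean intensities are classified into background / mid / bright tiers
    by multi-Otsu on the whole volume; bright regions are fused across
    slices by 3D connected components into tooth structures (up to
    ``max_teeth``, largest first, mirroring a target molar plus its
    neighbour), and each fully enclosed low-intensity cavity inside a
    tooth becomes its pulp.

    Legend: 0 background, 1 alveolar (mid-intensity bulk, if any), then
    one label per tooth component ("tooth") followed by one per pulp
    cavity ("pulp").
    """
    v = vol.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        warnings.warn("volume is constant; nothing to segment", stacklevel=2)
        return LabelVolume(np.zeros(v.shape, dtype=int), {0: "background"}, vol.spacing)
    scaled = (v - lo) / (hi - lo) * 255.0

    region_mean = np.zeros_like(scaled)
    for i, sl in enumerate(scaled):
        if sl.var() < 1e-12 or sl.mean() <= 0:
            continue
        params = scm_adaptive_params(sl + 1.0, C=C, a=a, n_iter=n_iter)
        labels, _ = scm_segment_slice(sl + 1.0, params)
        present = np.unique(labels)
        means = np.zeros(labels.max() + 1)
        means[present] = ndimage.mean(sl, labels=labels, index=present)
        region_mean[i] = means[labels]

    try:
        t1, t2 = threshold_multiotsu(scaled, classes=3)
    except ValueError:  # not enough distinct grey levels
        t1 = t2 = 0.5 * (scaled.min() + scaled.max())
    bright = region_mean > t2
    mid = (region_mean > t1) & ~bright

    out = np.zeros(v.shape, dtype=int)
    legend = {0: "background"}
    comp, n_comp = ndimage.label(bright)
    if n_comp == 0:
        warnings.warn("no tooth-intensity structure found", stacklevel=2)
        return LabelVolume(out, legend, vol.spacing)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1] + 1
    teeth = [int(c) for c in order[:max_teeth] if sizes[c - 1] >= min_component_voxels]

    # mid-intensity bulk outside teeth = alveolar bone analogue
    alveolar = mid.copy()
    next_label = 2
    tooth_labels, pulp_masks = [], []
    for c in teeth:
        tooth_mask = comp == c
        filled = ndimage.binary_fill_holes(tooth_mask)
        cavity = filled & ~tooth_mask
        alveolar &= ~filled
        out[tooth_mask] = next_label
        legend[next_label] = "tooth"
        tooth_labels.append(next_label)
        next_label += 1
        cav_comp, n_cav = ndimage.label(cavity)
        if n_cav:
            cav_sizes = ndimage.sum_labels(np.ones_like(cav_comp), cav_comp,
                                           index=np.arange(1, n_cav + 1))
            keep = [i + 1 for i, s in enumerate(cav_sizes) if s >= min_component_voxels]
            if keep:
                pulp_masks.append(np.isin(cav_comp, keep))
            else:
                pulp_masks.append(None)
        else:
            pulp_masks.append(None)
    if not any(m is not None for m in pulp_masks):
        warnings.warn("no pulp-candidate cavity found inside any tooth", stacklevel=2)
    for m in pulp_masks:
        if m is None:
            continue
        out[m] = next_label
        legend[next_label] = "pulp"
        next_label += 1
    if alveolar.sum() >= 10 * min_component_voxels:
        out[alveolar & (out == 0)] = 1
        legend[1] = "alveolar"
    return LabelVolume(out, legend, vol.spacing)


# ---------------------------------------------------------------------------
# surface extraction


def _laplacian_smooth(verts: np.ndarray, faces: np.ndarray, iters: int,
                      lam: float = 0.5) -> np.ndarray:
    if iters == 0:
        return verts
    n = len(verts)
    # symmetric vertex adjacency from triangle edges
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    deg = np.bincount(i, minlength=n).astype(float)
    deg[deg == 0] = 1.0
    v = verts.copy()
    for _ in range(iters):
        acc = np.zeros_like(v)
        np.add.at(acc, i, v[j])
        v += lam * (acc / deg[:, None] - v)
    return v


def extract_surface_cloud(labels: LabelVolume, which, smoothing_iters: int = 10) -> PointCloud:
    """Marching-cubes isosurface of one labelled structure as a point cloud.

    The binary mask is contoured at 0.5, vertices are scaled into mm by
    the voxel spacing, Laplacian-smoothed (umbrella operator, lambda 0.5)
    for ``smoothing_iters`` passes, and per-vertex outward normals are
    averaged from the triangle normals.
    """
    mask = labels.mask_for(which)
    if not mask.any():
        raise ValueError(f"label {which!r} selects no voxels")
    try:
        verts, faces, _, _ = marching_cubes(
            mask.astype(float), level=0.5, spacing=tuple(labels.spacing))
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"no surface found for label {which!r}") from exc
    if len(verts) == 0:
        raise ValueError(f"empty surface for label {which!r}")
    verts = _laplacian_smooth(verts, faces, smoothing_iters)
    mesh = trimesh.Trimesh(verts, faces, process=False)
    normals = np.asarray(mesh.vertex_normals, dtype=float).copy()
    outward = verts - verts.mean(axis=0)
    bad = np.linalg.norm(normals, axis=1) < 1e-12
    if bad.any():  # isolated vertices: fall back to the radial direction
        normals[bad] = outward[bad]
        still = np.linalg.norm(normals, axis=1) < 1e-12
        normals[still] = (0.0, 0.0, 1.0)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient outward (majority vote against the centroid direction)
    if np.sum(np.einsum("ij,ij->i", normals, outward) < 0) > len(verts) / 2:
        normals = -normals
    tag = "cbct_pulp" if (isinstance(which, str) and which == "pulp") else "cbct_crown"
    return PointCloud(verts, normals, tag)
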