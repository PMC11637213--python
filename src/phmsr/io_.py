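"""File formats: STL/PLY meshes, point clouds, DICOM volumes, transforms.

Meshes go through trimesh (binary and ASCII dialects of both STL and
PLY); point clouds are stored as PLY vertex clouds or plain XYZ text;
DICOM series are read slice-per-file with slope/intercept rescaling;
rigid transforms serialise as row-major 4x4 homogeneous matrices in
JSON. Volumes without DICOM metadata round-trip through a .npz + JSON
sidecar pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import trimesh

from .geometry_core import PointCloud, RigidTransform
from .volume_preprocess import LabelVolume, VolumeImage

__all__ = [
    "read_mesh", "write_mesh", "read_point_cloud", "write_point_cloud",
    "read_dicom_volume", "read_volume", "write_volume",
    "read_transform_json", "write_transform_json",
]

_MESH_EXTS = {".stl", ".ply"}


def read_mesh(path) -> trimesh.Trimesh:
    """Load an STL or PLY mesh (either dialect)."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise ValueError(f"unsupported mesh extension {path.suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # STL stores a triangle soup; merge duplicate vertices on load so
        # a write/read round-trip preserves the vertex count. PLY keeps
        # its explicit vertex list untouched.
        mesh = trimesh.load_mesh(path, process=path.suffix.lower() == ".stl")
    except Exception as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise ValueError(f"{path} does not contain a triangle mesh")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise ValueError(f"unsupported mesh extension {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)


def read_point_cloud(path, source_tag: str = "other") -> PointCloud:
    """Load a cloud from PLY (vertices) or whitespace XYZ text."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        pts = np.loadtxt(path, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(1, -1)
        return PointCloud(pts[:, :3], None, source_tag)
    loaded = trimesh.load(path, process=False)
    pts = np.asarray(loaded.vertices, dtype=float)
    if len(pts) == 0:
        raise ValueError(f"{path} contains no points")
    return PointCloud(pts, None, source_tag)


def write_point_cloud(cloud: PointCloud, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
    else:
        trimesh.PointCloud(cloud.points).export(path)


def read_dicom_volume(directory) -> VolumeImage:
    """Read a single-frame-per-file DICOM series into a volume.

    Slices are sorted by slice location (not filename); intensities are
    rescaled by slope/intercept; inconsistent in-plane spacing or a gap
    in the slice spacing raises naming the offending slice.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        slices.append((f, ds))
    if not slices:
        raise ValueError(f"no DICOM image slices found in {directory}")

    def location(item):
        _, ds = item
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    slices.sort(key=location)
    first = slices[0][1]
    px_spacing = [float(v) for v in first.PixelSpacing]
    locs = [location(s) for s in slices]
    if len(slices) > 1:
        steps = np.diff(locs)
        step = np.median(steps)
        for (f, _), d in zip(slices[1:], steps):
            if abs(d - step) > 0.25 * abs(step):
                raise ValueError(f"slice spacing gap at {f.name}: "
                                 f"step {d:.4f} vs expected {step:.4f}")
        dz = abs(step)
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    arrs = []
    for f, ds in slices:
        if [float(v) for v in ds.PixelSpacing] != px_spacing:
            raise ValueError(f"inconsistent pixel spacing in {f.name}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(ds.pixel_array.astype(float) * slope + intercept)
    vox = np.stack(arrs)
    return VolumeImage(vox, (dz, px_spacing[0], px_spacing[1]))


def write_volume(vol, path) -> None:
    """Store a VolumeImage or LabelVolume as .npz (+ spacing/legend inside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        np.savez_compressed(path, labels=vol.labels, spacing=vol.spacing,
                            legend=json.dumps({str(k): v for k, v in vol.legend.items()}))
    else:
        np.savez_compressed(path, voxels=vol.voxels, spacing=vol.spacing)


def read_volume(path):
    path = Path(path)
    with np.load(path, allow_pickle=False) as data:
        if "labels" in data:
            legend = {int(k): v for k, v in json.loads(str(data["legend"])).items()}
            return LabelVolume(data["labels"], legend, data["spacing"])
        return VolumeImage(data["voxels"], data["spacing"])


def write_transform_json(T: RigidTransform, path, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"matrix": T.as_matrix().tolist(), "order": "row-major"}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))


def read_transform_json(path) -> RigidTransform:
    data = json.loads(Path(path).read_text())
    return RigidTransform.from_matrix(np.asarray(data["matrix"], dtype=float))
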