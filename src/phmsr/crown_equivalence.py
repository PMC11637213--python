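"""Equivalent-crown carving from OBB alignment.

An intraoral scan sees only the clinical crown, while the CBCT
segmentation yields the whole tooth. Before registration the CBCT tooth
is reduced to the "equivalent crown": the scan crown's oriented bounding
box is aligned to the CBCT tooth's box (prongs parallel, centre moved to
the CBCT centre in x/y while keeping the scan's own z), and the CBCT
cloud is cut at the aligned box's bottom face, keeping the occlusal side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry_core import (OrientedBoundingBox, PointCloud, RigidTransform,
                            _project_so3)

__all__ = ["EquivalenceResult", "align_obb_centers", "crop_crown_by_obb_base"]


@dataclass
class EquivalenceResult:
    aligning_transform: RigidTransform
    cut_plane: tuple[np.ndarray, np.ndarray]  # (point, occlusal unit normal)
    cropped_cbct_crown: PointCloud
    retained_indices: np.ndarray | None = None


def align_obb_centers(scan_obb: OrientedBoundingBox,
                      cbct_obb: OrientedBoundingBox) -> RigidTransform:
    """Rigid transform aligning the scan OBB to the CBCT OBB.

    Rotation maps the scan box axes onto the CBCT box axes (so the A-D
    and A-B prongs of the two boxes become parallel); the scan centre is
    then moved to (x_ct, y_ct, z_op) — x and y taken from the CBCT box,
    z kept from the scan box. Near-180° prong flips are resolved by the
    minimal-rotation choice.
    """
    R = cbct_obb.axes.T @ scan_obb.axes
    if np.linalg.det(R) < 0:  # canonicalised axes are right-handed; guard anyway
        R = cbct_obb.axes.T @ (scan_obb.axes * np.array([[1], [1], [-1]]))
    R = _project_so3(R)
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
    if angle > 175.0:
        warnings.warn("OBB prongs nearly antiparallel; 180-degree ambiguity "
                      "resolved by the minimal rotation", stacklevel=2)
    c_op, c_ct = scan_obb.center, cbct_obb.center
    target = np.array([c_ct[0], c_ct[1], c_op[2]])
    t = target - R @ c_op
    return RigidTransform(R, t)


def crop_crown_by_obb_base(cbct_tooth: PointCloud,
                           scan_obb_after_alignment: OrientedBoundingBox,
                           ) -> EquivalenceResult:
    """Keep the CBCT points on the occlusal side of the scan box's base.

    The cut plane is the aligned scan OBB's bottom face A'B'C'D' with its
    normal pointing occlusally; points with non-negative signed distance
    are retained. An empty result signals misalignment and raises.
    """
    if len(cbct_tooth) == 0:
        raise ValueError("CBCT tooth cloud is empty")
    point, normal = scan_obb_after_alignment.bottom_face
    signed = (cbct_tooth.points - point) @ normal
    keep = signed >= 0.0
    if not keep.any():
        raise ValueError("cut plane removed every CBCT point; "
                         "OBB alignment is likely wrong")
    normals = None if cbct_tooth.normals is None else cbct_tooth.normals[keep]
    cropped = PointCloud(cbct_tooth.points[keep], normals, cbct_tooth.source_tag)
    return EquivalenceResult(
        aligning_transform=RigidTransform.identity(),
        cut_plane=(point, normal),
        cropped_cbct_crown=cropped,
        retained_indices=np.nonzero(keep)[0],
    )
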