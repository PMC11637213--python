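"""Registration accuracy metrics: crown RMSE and crown-pulp pose deviation.

Crown RMSE is the root-mean-square nearest-neighbour distance from each
fixed (CBCT) crown point to the registered scan cloud. The crown-pulp
metrics quantify how much the *relative* pose of the scan crown with
respect to the CBCT pulp differs between the registered and the
ground-truth alignment: principal-component frames are fitted to the
pulp cloud and to both crown poses, and

    CPPD = || per-axis position deviation ||  (mm)
    CPOD = || per-axis orientation deviation || (degrees)

where the per-axis terms are the differences of the crown-minus-pulp
centre offsets and of the crown-frame Euler angles (ZYX intrinsic,
measured relative to the pulp frame) between the two poses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry_core import PointCloud, RigidTransform, pca_frame

__all__ = ["PoseDeviation", "rmse", "crown_pulp_deviation", "evaluate_run",
           "transform_errors", "summarize_runs", "write_metrics_csv"]


@dataclass
class PoseDeviation:
    """Crown-pulp position (mm) / orientation (deg) deviation with axis terms."""

    cppd: float
    cpod: float
    per_axis_position: np.ndarray
    per_axis_orientation: np.ndarray

    def __post_init__(self):
        self.per_axis_position = np.asarray(self.per_axis_position, dtype=float)
        self.per_axis_orientation = np.asarray(self.per_axis_orientation, dtype=float)


def rmse(cbct_crown: PointCloud, registered_scan: PointCloud) -> float:
    """Root-mean-square nearest-neighbour distance (mm).

    For each fixed CBCT point the nearest point of the registered scan
    cloud is its pair; pairs are not required to be unique.
    """
    if len(cbct_crown) == 0 or len(registered_scan) == 0:
        raise ValueError("both clouds must be nonempty")
    d, _ = registered_scan.kdtree().query(cbct_crown.points)
    return float(np.sqrt(np.mean(d ** 2)))


def _euler_zyx_deg(R: np.ndarray) -> np.ndarray:
    """Intrinsic ZYX Euler angles (alpha, beta, gamma) in degrees."""
    beta = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(R[2, 0]) < 1.0 - 1e-12:
        alpha = np.arctan2(R[1, 0], R[0, 0])
        gamma = np.arctan2(R[2, 1], R[2, 2])
    else:  # gimbal lock: fold everything into alpha
        alpha = np.arctan2(-R[0, 1], R[1, 1])
        gamma = 0.0
    return np.degrees(np.array([alpha, beta, gamma]))


def _crown_frame_in_pulp(crown: PointCloud, pulp_frame,
                         reference_axes: np.ndarray | None = None,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crown centre (pulp-frame coords), crown-in-pulp rotation, crown axes.

    Crown principal axes are sign-canonicalised against ``reference_axes``
    (the pulp axes by default, or the truth-pose crown axes for the
    registered pose, whose axes are nearly parallel so the sign choice is
    robust) — never against the global axes, which would break invariance
    under a common rigid motion of all clouds.
    """
    f = pca_frame(crown)
    ref = pulp_frame.axes if reference_axes is None else reference_axes
    axes = f.axes.copy()
    for i in range(2):
        if np.dot(axes[i], ref[i]) < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    R_rel = pulp_frame.axes @ axes.T  # crown frame expressed in pulp frame
    center_rel = pulp_frame.axes @ (f.origin - pulp_frame.origin)
    return center_rel, R_rel, axes


def crown_pulp_deviation(pulp: PointCloud, crown_truth_pose: PointCloud,
                         crown_registered: PointCloud) -> PoseDeviation:
    """Crown-pulp pose deviation between a registered and the true pose.

    ``crown_truth_pose`` and ``crown_registered`` must be the same crown
    cloud in two poses; the pulp cloud defines the reference frame.
    Deviations are expressed in the pulp frame, so a common rigid
    transform of all three clouds leaves them unchanged.
    """
    for c in (pulp, crown_truth_pose, crown_registered):
        if len(c) < 4:
            raise ValueError("clouds need at least 4 points for PCA frames")
    pf = pca_frame(pulp)
    c_t, R_t, t_axes = _crown_frame_in_pulp(crown_truth_pose, pf)
    c_a, R_a, _ = _crown_frame_in_pulp(crown_registered, pf,
                                       reference_axes=t_axes)
    d_pos = c_a - c_t
    d_ang = _euler_zyx_deg(R_a) - _euler_zyx_deg(R_t)
    d_ang = (d_ang + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    return PoseDeviation(
        cppd=float(np.linalg.norm(d_pos)),
        cpod=float(np.linalg.norm(d_ang)),
        per_axis_position=d_pos,
        per_axis_orientation=d_ang,
    )


def transform_errors(estimate: RigidTransform, truth: RigidTransform,
                     reference_point=None) -> tuple[float, float]:
    """(rotation error [deg], translation error [mm]) of an estimate.

    The registration of a cloud perturbed by ``truth`` should recover
    ``truth.inverse()``; the residual motion is estimate o truth. Its
    rotation angle is the rotation error, and its displacement at
    ``reference_point`` (default: the origin of ``truth``'s action,
    i.e. 0) is the translation error, which avoids lever-arm ambiguity.
    """
    resid = estimate.compose(truth)
    rot = resid.rotation_angle_deg()
    ref = np.zeros(3) if reference_point is None else np.asarray(reference_point, float)
    trans = float(np.linalg.norm(resid.apply(ref) - ref))
    return rot, trans


def evaluate_run(result, truth: RigidTransform | None, clouds: dict,
                 seed: int | None = None, preset: str | None = None) -> dict:
    """One tabular metrics row for a registration run.

    ``clouds`` must contain "cbct_crown" and "scan" (original, unmoved
    source) and may contain "pulp" and "scan_perturbed" (the actual
    registration input). With a ground truth available the crown-pulp
    deviations are computed; without one (real-data runs) those fields
    stay empty and only the RMSE is reported.
    """
    cbct = clouds["cbct_crown"]
    scan = clouds["scan"]
    moved_input = clouds.get("scan_perturbed", scan)
    from .geometry_core import apply_transform
    registered = apply_transform(moved_input, result.transform)
    row = {
        "method": result.method,
        "preset": preset,
        "seed": seed,
        "rmse_mm": rmse(cbct, registered),
        "cppd_mm": None,
        "cpod_deg": None,
        "rotation_error_deg": None,
        "translation_error_mm": None,
        "iterations": result.n_iterations,
        "converged": result.converged,
    }
    if truth is not None:
        pulp = clouds.get("pulp")
        if pulp is not None:
            dev = crown_pulp_deviation(pulp, scan, registered)
            row["cppd_mm"] = dev.cppd
            row["cpod_deg"] = dev.cpod
        rot, trans = transform_errors(result.transform, truth,
                                      reference_point=scan.centroid)
        row["rotation_error_deg"] = rot
        row["translation_error_mm"] = trans
    return row


def summarize_runs(rows: list[dict]) -> dict:
    """Mean +/- SD of each numeric metric grouped by (method, preset)."""
    groups: dict = {}
    for r in rows:
        groups.setdefault((r["method"], r.get("preset")), []).append(r)
    out = {}
    for (method, preset), rs in groups.items():
        entry = {"n": len(rs)}
        for key in ("rmse_mm", "cppd_mm", "cpod_deg",
                    "rotation_error_deg", "translation_error_mm"):
            vals = [r[key] for r in rs if r.get(key) is not None]
            if vals:
                entry[key] = {"mean": float(np.mean(vals)),
                              "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        out[f"{method}/{preset}"] = entry
    return out


_CSV_FIELDS = ["method", "preset", "seed", "rmse_mm", "cppd_mm", "cpod_deg",
               "rotation_error_deg", "translation_error_mm", "iterations",
               "converged"]


def write_metrics_csv(rows: list[dict], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for r in rows:
            writer.writerow({k: r.get(k) for k in _CSV_FIELDS})
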