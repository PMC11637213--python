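"""Seeded end-to-end benchmark harness over synthetic tooth phantoms.

One *case* = one phantom + one scan cloud + one CBCT crown/pulp pair +
one seeded pose perturbation of the scan. Each registration method is
run on the same case and scored with the crown RMSE and the crown-pulp
pose deviations (CPOD/CPPD) against the known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic_data as sdata
from .baselines import cpd_rigid_register, icp_register, sparse_icp_register
from .evaluation import evaluate_run, summarize_runs
from .geometry_core import PointCloud
from .registration import register_phmsr

__all__ = ["PhantomCase", "make_case", "run_method", "run_benchmark"]

METHODS = ("phmsr", "sicp", "icp", "cpd")


@dataclass
class PhantomCase:
    clouds: dict
    truth: object  # RigidTransform applied to the scan
    seed: int
    preset: str


def make_case(seed: int, preset: str = "small", *,
              scan_density: float = 60.0,
              cbct_outlier_frac: float = 0.0,
              cbct_dropout_frac: float = 0.0,
              n_cusps: int = 4,
              crown_diameter_mm: float = 10.0) -> PhantomCase:
    """Build one reproducible phantom registration case.

    Sub-seeds for the phantom, the two clouds and the perturbation are
    derived from ``seed`` so cases never share randomness.
    """
    ph = sdata.make_tooth_phantom(n_cusps, crown_diameter_mm, seed=seed)
    scan = sdata.make_scan_cloud(ph, scan_density, seed=seed + 10_000)
    crown, pulp = sdata.make_cbct_cloud(
        ph, outlier_frac=cbct_outlier_frac, dropout_frac=cbct_dropout_frac,
        seed=seed + 20_000)
    moved, truth = sdata.perturb_pose(scan, preset, seed=seed + 30_000)
    clouds = {"scan": scan, "scan_perturbed": moved,
              "cbct_crown": crown, "pulp": pulp}
    return PhantomCase(clouds, truth, seed, preset)


def run_method(method: str, case: PhantomCase, *, cpd_max_points: int = 1500,
               **overrides):
    """Run one registration method on a case; returns RegistrationResult."""
    moved = case.clouds["scan_perturbed"]
    crown = case.clouds["cbct_crown"]
    if method == "phmsr":
        return register_phmsr(moved, crown, case.clouds["pulp"],
                              case.preset, **overrides)
    if method == "sicp":
        return sparse_icp_register(moved, crown, **overrides)
    if method == "icp":
        return icp_register(moved, crown, **overrides)
    if method == "cpd":
        rng = np.random.default_rng(case.seed + 40_000)
        src, tgt = moved, crown
        if len(src) > cpd_max_points:
            src = PointCloud(src.points[rng.choice(len(src), cpd_max_points,
                                                   replace=False)])
        if len(tgt) > cpd_max_points:
            tgt = PointCloud(tgt.points[rng.choice(len(tgt), cpd_max_points,
                                                   replace=False)])
        return cpd_rigid_register(src, tgt, **overrides)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(seeds, presets=("small",), methods=METHODS, *,
                  scan_density: float = 60.0,
                  cbct_outlier_frac: float = 0.0,
                  cbct_dropout_frac: float = 0.0,
                  cpd_max_points: int = 1500) -> tuple[list[dict], dict]:
    """All methods x presets x seeds; returns (rows, summary)."""
    rows = []
    for preset in presets:
        for seed in seeds:
            case = make_case(seed, preset, scan_density=scan_density,
                             cbct_outlier_frac=cbct_outlier_frac,
                             cbct_dropout_frac=cbct_dropout_frac)
            for method in methods:
                res = run_method(method, case, cpd_max_points=cpd_max_points)
                rows.append(evaluate_run(res, case.truth, case.clouds,
                                         seed=seed, preset=preset))
    return rows, summarize_runs(rows)
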