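"""Comparison registration methods: classic ICP, sparse ICP, rigid CPD.

All three share the :class:`~phmsr.registration.RegistrationResult`
schema and the convention that the *source* cloud is moved onto the
*target* cloud, so the evaluation harness is method-agnostic.
"""

from __future__ import annotations

import numpy as np

from .geometry_core import PointCloud, RigidTransform
from .registration import (CorrespondenceSet, RegistrationResult,
                           SparseIcpState, admm_sparse_solve, kabsch)

__all__ = ["icp_register", "sparse_icp_register", "cpd_rigid_register"]


def icp_register(source: PointCloud, target: PointCloud,
                 max_iter: int = 100, tol_mm: float = 0.1) -> RegistrationResult:
    """Classic point-to-point ICP.

    Nearest-neighbour correspondences plus the closed-form SVD (Kabsch)
    update per iteration; stops once the mean residual reaches the
    allowable error ``tol_mm`` (default 0.1 mm), when the residual
    stagnates, or after ``max_iter`` iterations (default 100).
    """
    if len(source) < 3 or len(target) < 3:
        raise ValueError("both clouds need at least 3 points")
    tree = target.kdtree()
    T = RigidTransform.identity()
    pts = source.points.copy()
    history = []
    prev_mean = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d, idx = tree.query(pts)
        T_inc = kabsch(pts, target.points[idx])
        pts = T_inc.apply(pts)
        T = T_inc.compose(T)
        d_new, _ = tree.query(pts)
        mean_resid = float(d_new.mean())
        history.append({"iteration": it, "mean_residual_mm": mean_resid,
                        "transform": T.as_matrix()})
        if mean_resid < tol_mm or abs(prev_mean - mean_resid) < 1e-7:
            converged = True
            break
        prev_mean = mean_resid
    return RegistrationResult(T, converged, it, "icp", history)


def sparse_icp_register(source: PointCloud, target: PointCloud,
                        p: float = 0.5, mu: float = 10.0,
                        n2: int = 2, ns: int = 3,
                        max_outer: int = 50,
                        rot_tol_deg: float = 0.01,
                        trans_tol_mm: float = 1e-3) -> RegistrationResult:
    """Sparse l_p ICP with plain nearest-neighbour correspondences.

    Identical ADMM solver to the PHMSR core, but without mapping
    surfaces or PHFM weighting: every free point is matched to its
    nearest target point. Defaults p = 0.5, mu = 10, n2 = 2, ns = 3.
    """
    if len(source) < 3 or len(target) < 3:
        raise ValueError("both clouds need at least 3 points")
    tree = target.kdtree()
    state = SparseIcpState(p=p, mu=mu, n2=n2, ns=ns)
    T = RigidTransform.identity()
    pts = source.points.copy()
    centroid = source.centroid
    history = []
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        T_start = T
        for _ in range(n2):
            _, idx = tree.query(pts)
            corr = CorrespondenceSet(target.points[idx], pts,
                                     np.arange(len(pts)))
            state.reset(len(corr))
            T_inc, state = admm_sparse_solve(corr, state)
            pts = T_inc.apply(pts)
            T = T_inc.compose(T)
        delta = T.compose(T_start.inverse())
        rot_inc = delta.rotation_angle_deg()
        trans_inc = float(np.linalg.norm(delta.apply(centroid) - centroid))
        d, _ = tree.query(pts)
        history.append({"iteration": n_outer,
                        "mean_residual_mm": float(d.mean()),
                        "transform": T.as_matrix()})
        if rot_inc < rot_tol_deg and trans_inc < trans_tol_mm:
            converged = True
            break
    return RegistrationResult(T, converged, n_outer, "sparse_icp", history)


def cpd_rigid_register(source: PointCloud, target: PointCloud,
                       outlier_weight: float = 0.1, max_iter: int = 100,
                       tol: float = 1e-6) -> RegistrationResult:
    """Rigid coherent point drift (GMM EM, no scaling).

    The moving source points are Gaussian mixture centroids with a
    shared isotropic variance sigma^2; a uniform component of weight
    ``outlier_weight`` absorbs outliers. The M-step rotation comes from
    an SVD, and iterations stop when the negative log-likelihood changes
    by less than ``tol`` (relative) or sigma^2 underflows.
    """
    X = target.points  # (N, 3) fixed
    Y0 = source.points  # (M, 3) moving
    if len(X) == 0 or len(Y0) == 0:
        raise ValueError("clouds must be nonempty")
    N, M = len(X), len(Y0)
    w = float(outlier_weight)
    if not (0.0 <= w < 1.0):
        raise ValueError("outlier_weight must be in [0, 1)")
    T = RigidTransform.identity()
    Y = Y0.copy()
    sigma2 = (N * (Y ** 2).sum() + M * (X ** 2).sum()
              - 2.0 * X.sum(0) @ Y.sum(0)) / (3.0 * N * M)
    # uniform outlier density over the target bounding volume
    extent = np.maximum(X.max(0) - X.min(0), 1e-6)
    uniform = 1.0 / float(np.prod(extent))
    history = []
    prev_nll = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)  # (N, M)
        gauss = np.exp(-d2 / (2.0 * sigma2)) / ((2.0 * np.pi * sigma2) ** 1.5)
        mixture = (1.0 - w) * gauss.mean(axis=1) + w * uniform
        mixture = np.maximum(mixture, 1e-300)
        nll = -float(np.log(mixture).sum())
        history.append({"iteration": it, "nll": nll, "sigma2": float(sigma2),
                        "transform": T.as_matrix()})
        if prev_nll - nll < tol * max(abs(prev_nll), 1.0) and it > 1:
            converged = True
            break
        prev_nll = nll
        P = (1.0 - w) * gauss / M
        P = P / mixture[:, None]  # (N, M) posteriors
        Np = P.sum()
        P1 = P.sum(axis=0)   # (M,)
        Pt1 = P.sum(axis=1)  # (N,)
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y0) / Np
        Xh = X - mu_x
        Yh = Y0 - mu_y
        A = Xh.T @ P @ Yh
        U, _, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt
        t = mu_x - R @ mu_y
        T = RigidTransform(R, t)
        Y = T.apply(Y0)
        sigma2_new = ((Pt1 @ (Xh ** 2).sum(1)) - 2.0 * np.trace(A.T @ R)
                      + (P1 @ (Yh ** 2).sum(1))) / (3.0 * Np)
        if sigma2_new < 1e-12:
            converged = True
            sigma2 = max(sigma2_new, 1e-12)
            break
        sigma2 = sigma2_new
    return RegistrationResult(T, converged, it, "cpd", history)
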