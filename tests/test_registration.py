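import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phmsr.geometry_core import (DegenerateGeometryError, PointCloud,
                                 RigidTransform, estimate_normals)
from phmsr.registration import (CorrespondenceSet, MappingSelection,
                                PulpHornFeature, SparseIcpState,
                                admm_sparse_solve, fit_mls_patch, kabsch,
                                lp_alignment_cost, match_point_to_surface,
                                phfm_select_mapping_points,
                                pulp_horn_feature_directions, register_phmsr,
                                sample_patch, PRESETS)
from phmsr.synthetic_data import make_tooth_phantom, make_scan_cloud


class TestPulpHornFeatures:
    def test_single_conical_horn_direction(self, rng):
        # cone apex along +z on top of a small ball of points
        theta = rng.uniform(0, 2 * np.pi, 800)
        h = rng.uniform(0, 1, 800)
        r = (1 - h) * 0.8
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), 2 * h])
        feats = pulp_horn_feature_directions(PointCloud(pts), [0, 0, 1], 1)
        ang = np.degrees(np.arccos(np.clip(feats[0].direction @ [0, 0, 1], -1, 1)))
        assert ang < 2.0

    def test_manual_overrides_pass_through(self):
        manual = [PulpHornFeature([0, 0, 1], [0, 0, 1], "manual")] * 4
        out = pulp_horn_feature_directions(
            PointCloud(np.zeros((1, 3))), [0, 0, 1], 4, manual_overrides=manual)
        assert out == manual

    def test_four_horn_phantom_apexes(self, phantom):
        pulp = PointCloud(phantom.pulp_mesh.vertices, source_tag="cbct_pulp")
        feats = pulp_horn_feature_directions(pulp, phantom.occlusal_axis, 4)
        found = np.array([f.apex for f in feats])
        for apex in phantom.horn_apexes:
            assert np.linalg.norm(found - apex, axis=1).min() < 0.3

    def test_too_few_maxima_raises_with_count(self):
        # a single horn cannot yield four
        pts = np.column_stack([np.zeros(50), np.zeros(50), np.linspace(0, 2, 50)])
        with pytest.raises(ValueError, match="1"):
            pulp_horn_feature_directions(PointCloud(pts + 1e-3), [0, 0, 1], 4)


@pytest.fixture(scope="module")
def crown_with_normals(cbct_clouds):
    crown, _ = cbct_clouds
    return crown if crown.normals is not None else estimate_normals(crown)


class TestPhfmSelection:
    def test_gamma_180_retains_everything(self, crown_with_normals):
        horns = [PulpHornFeature([0, 0, 3], [0, 0, 1])]
        sel = phfm_select_mapping_points(crown_with_normals, horns, 180.0)
        assert len(sel.indices) == len(crown_with_normals)

    def test_normal_equal_to_horn_direction_retained(self):
        normals = np.array([[0, 0, 1.0], [1.0, 0, 0]])
        cloud = PointCloud(np.array([[0, 0, 1.0], [1.0, 0, 0]]), normals)
        horns = [PulpHornFeature([0, 0, 1], [0, 0, 1])]
        sel = phfm_select_mapping_points(cloud, horns, 20.0)
        assert 0 in sel.indices and 1 not in sel.indices

    def test_matches_bruteforce_angle_oracle(self, rng):
        n = rng.normal(size=(1000, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cloud = PointCloud(rng.normal(size=(1000, 3)), n)
        horns = [PulpHornFeature(rng.normal(size=3), rng.normal(size=3))
                 for _ in range(3)]
        gamma = 35.0
        sel = phfm_select_mapping_points(cloud, horns, gamma)
        oracle = set()
        for i in range(1000):
            for h in horns:
                c = float(np.dot(n[i], h.direction))
                ang = np.degrees(np.arccos(max(-1.0, min(1.0, c))))
                if ang <= gamma:
                    oracle.add(i)
                    break
        assert set(sel.indices.tolist()) == oracle

    def test_empty_selection_raises(self):
        normals = np.tile([0, 0, 1.0], (10, 1))
        cloud = PointCloud(np.random.default_rng(0).normal(size=(10, 3)), normals)
        horns = [PulpHornFeature([1, 0, 0], [1, 0, 0])]
        with pytest.raises(ValueError, match="gamma"):
            phfm_select_mapping_points(cloud, horns, 5.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_phfm_retention_monotone_in_gamma(seed):
    rng = np.random.default_rng(seed)
    n = rng.normal(size=(200, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    cloud = PointCloud(rng.normal(size=(200, 3)), n)
    horns = [PulpHornFeature(rng.normal(size=3), rng.normal(size=3))]
    counts = []
    for gamma in (30.0, 60.0, 90.0, 150.0, 180.0):
        try:
            counts.append(len(phfm_select_mapping_points(cloud, horns, gamma).indices))
        except ValueError:
            counts.append(0)
    assert counts == sorted(counts)
    assert counts[-1] == 200


class TestMlsPatch:
    def _planar_cloud(self, rng, n=60, radius=1.0):
        xy = rng.uniform(-radius, radius, (n, 2))
        return PointCloud(np.column_stack([xy, np.zeros(n)]))

    def test_planar_neighbors_give_plane(self, rng):
        cloud = self._planar_cloud(rng)
        patch = fit_mls_patch(cloud, 0, fit_radius=2.0, min_neighbors=40)
        assert not patch.degenerate
        assert np.allclose(patch.quadric_coeffs[3:], 0.0, atol=1e-8)

    def test_paraboloid_coefficients_recovered(self):
        # symmetric lattice so the neighbourhood PCA frame is exactly xyz
        t = np.linspace(-0.5, 0.5, 15)
        gx, gy = np.meshgrid(t, t)
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        order = np.argsort(np.einsum("ij,ij->i", xy, xy), kind="stable")
        xy = xy[order]  # apex (0,0) first -> centre index 0
        z = (xy ** 2).sum(axis=1)
        cloud = PointCloud(np.column_stack([xy, z]))
        patch = fit_mls_patch(cloud, 0, fit_radius=2.0,
                              min_neighbors=len(xy) - 1)
        a = patch.quadric_coeffs
        # the quadratic form is isotropic, so any in-plane frame rotation
        # leaves a3 = a5, a4 = 0; the normal sign only flips the sign
        assert abs(abs(a[3]) - 1.0) < 1e-6
        assert abs(a[3] - a[5]) < 1e-6
        assert abs(a[4]) < 1e-6

    def test_too_few_neighbors_sets_fallback(self, rng):
        pts = rng.normal(size=(5, 3))
        cloud = PointCloud(pts)
        patch = fit_mls_patch(cloud, 0, fit_radius=100.0, min_neighbors=10)
        assert patch.degenerate

    def test_radius_excludes_neighbors(self, rng):
        cloud = self._planar_cloud(rng, radius=5.0)
        patch = fit_mls_patch(cloud, 0, fit_radius=1e-6, min_neighbors=40)
        assert patch.degenerate


class TestSamplePatch:
    @pytest.fixture()
    def plane_patch(self, rng):
        xy = np.random.default_rng(1).uniform(-1, 1, (80, 2))
        cloud = PointCloud(np.column_stack([xy, 0.1 * xy[:, 0]]))
        return fit_mls_patch(cloud, 0, fit_radius=3.0, min_neighbors=60)

    def test_span_larger_than_disk_gives_single_sample(self, plane_patch):
        with pytest.warns(UserWarning):
            out = sample_patch(plane_patch, sample_radius=0.1, span=0.5)
        assert len(out.samples) == 1

    def test_sample_count_matches_lattice_oracle(self, plane_patch):
        r_s, d_s = 0.3, 0.1
        out = sample_patch(plane_patch, r_s, d_s)
        count = 0
        m = int(np.floor(r_s / d_s))
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                if (i * d_s) ** 2 + (j * d_s) ** 2 <= r_s ** 2 + 1e-12:
                    count += 1
        assert len(out.samples) == count

    def test_samples_satisfy_quadric_in_local_frame(self, plane_patch):
        out = sample_patch(plane_patch, 0.4, 0.1)
        local = (out.samples - out.frame_origin) @ out.frame_axes.T
        z_pred = out.evaluate_local(local[:, 0], local[:, 1])
        assert np.allclose(local[:, 2], z_pred, atol=1e-6)


class TestMatchPointToSurface:
    def test_on_surface_point_self_match(self, rng):
        xy = rng.uniform(-2, 2, (400, 2))
        cloud = PointCloud(np.column_stack([xy, np.zeros(400)]))
        sel = MappingSelection(np.arange(400), 180.0)
        d_s = 0.1
        y = np.array([0.3, 0.2, 0.0])
        target, _ = match_point_to_surface(y, cloud, sel, r_fit=0.8,
                                           r_sample=0.8, d_sample=d_s)
        assert np.linalg.norm(target - y) <= d_s

    def test_planar_offset_projects_to_foot(self, rng):
        xy = rng.uniform(-2, 2, (500, 2))
        cloud = PointCloud(np.column_stack([xy, np.zeros(500)]))
        sel = MappingSelection(np.arange(500), 180.0)
        d_s = 0.05
        y = np.array([0.1, -0.2, 0.5])  # 0.5 mm above the plane
        target, _ = match_point_to_surface(y, cloud, sel, r_fit=1.0,
                                           r_sample=1.0, d_sample=d_s)
        foot = np.array([0.1, -0.2, 0.0])
        assert np.linalg.norm(target - foot) <= d_s / np.sqrt(2) + 1e-9

    def test_shrinking_radii_degenerate_to_nearest_neighbor(self, rng):
        pts = rng.normal(size=(500, 3)) * 3
        cloud = PointCloud(pts)
        tree = cloud.kdtree()
        sel = MappingSelection(np.arange(500), 180.0)
        eps = 1e-9
        same = 0
        queries = rng.normal(size=(100, 3)) * 3
        for y in queries:
            target, _ = match_point_to_surface(y, cloud, sel, r_fit=eps,
                                               r_sample=eps, d_sample=eps)
            _, nn = tree.query(y)
            if np.allclose(target, pts[nn]):
                same += 1
        assert same >= 99


class TestAdmmSparseSolve:
    def _corr(self, src, tgt):
        return CorrespondenceSet(tgt, src, np.arange(len(src)))

    def test_residual_free_gives_identity(self, rng):
        src = rng.normal(size=(50, 3))
        T, _ = admm_sparse_solve(self._corr(src, src.copy()),
                                 SparseIcpState(p=0.5))
        assert T.rotation_angle_deg() < 1e-9
        assert np.linalg.norm(T.translation) < 1e-9

    def test_p2_equals_procrustes_oracle(self, rng):
        src = rng.normal(size=(80, 3)) * 4
        T_true = RigidTransform.from_axis_angle([1, 0.3, 2], 25.0, [1, -2, 0.5])
        tgt = T_true.apply(src) + rng.normal(size=(80, 3)) * 0.1
        T, _ = admm_sparse_solve(self._corr(src, tgt), SparseIcpState(p=2.0))
        # independent oracle: unweighted Procrustes via scipy
        from scipy.spatial.transform import Rotation
        R_o, _ = Rotation.align_vectors(tgt - tgt.mean(0), src - src.mean(0))
        t_o = tgt.mean(0) - R_o.as_matrix() @ src.mean(0)
        assert np.abs(T.rotation - R_o.as_matrix()).max() < 1e-6
        assert np.abs(T.translation - t_o).max() < 1e-6

    def test_p_half_beats_p2_under_outliers(self, rng):
        src = rng.normal(size=(200, 3)) * 5
        T_true = RigidTransform.from_axis_angle([0.2, 1, 0.1], 10.0, [1, 0, -1])
        tgt = T_true.apply(src) + rng.normal(size=(200, 3)) * 0.02
        out = rng.choice(200, 40, replace=False)
        tgt[out] += rng.normal(size=(40, 3)) * 10.0
        corr = self._corr(src, tgt)
        T2, _ = admm_sparse_solve(corr, SparseIcpState(p=2.0))
        state = SparseIcpState(p=0.5, ns=30)
        Th, _ = admm_sparse_solve(corr, state)
        err = lambda T: T.compose(T_true.inverse()).rotation_angle_deg()
        assert err(Th) < err(T2)

    def test_objective_non_increasing_with_safeguard(self, rng):
        src = rng.normal(size=(60, 3)) * 5
        tgt = src + rng.normal(size=(60, 3)) * 0.3
        tgt[:10] += 5.0
        corr = self._corr(src, tgt)
        state = SparseIcpState(p=0.5, ns=1)
        state.reset(len(corr))
        T = kabsch(src, tgt)
        costs = [lp_alignment_cost(corr, T, 0.5)]
        for _ in range(12):
            T, state = admm_sparse_solve(corr, state, initial=T)
            costs.append(lp_alignment_cost(corr, T, 0.5))
        assert all(b <= a + 1e-8 for a, b in zip(costs, costs[1:]))

    def test_collinear_correspondences_raise(self):
        t = np.linspace(0, 1, 10)
        src = np.outer(t, [1.0, 1.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            admm_sparse_solve(self._corr(src, src + 0.1), SparseIcpState(p=0.5))

    def test_default_parameters_match_published(self):
        state = SparseIcpState()
        assert (state.p, state.mu, state.n2, state.ns) == (0.5, 10.0, 2, 3)


class TestRegisterPhmsr:
    def test_presets_resolve_published_values(self):
        assert PRESETS["small"] == (20.0, 0.1)
        assert PRESETS["large"] == (25.0, 0.3)

    def test_exact_copy_recovers_identity(self, phantom):
        crown = make_scan_cloud(phantom, 20.0, noise_sigma_mm=0.0, seed=5)
        crown = PointCloud(crown.points, source_tag="cbct_crown")
        pulp = PointCloud(phantom.pulp_mesh.vertices, source_tag="cbct_pulp")
        scan = PointCloud(crown.points.copy(), source_tag="scan")
        res = register_phmsr(scan, crown, pulp, "small")
        assert res.converged
        assert res.transform.rotation_angle_deg() < 1e-6
        assert np.linalg.norm(res.transform.translation) < 1e-6

    def test_small_perturbation_recovery(self, phantom, scan_cloud, cbct_clouds):
        from phmsr.synthetic_data import perturb_pose
        from phmsr.evaluation import transform_errors
        crown, pulp = cbct_clouds
        moved, truth = perturb_pose(scan_cloud, "small", seed=2)
        res = register_phmsr(moved, crown, pulp, "small")
        rot, trans = transform_errors(res.transform, truth,
                                      scan_cloud.centroid)
        assert rot < 0.5 and trans < 0.1

    def test_unknown_preset_rejected(self, scan_cloud, cbct_clouds):
        crown, pulp = cbct_clouds
        with pytest.raises(ValueError):
            register_phmsr(scan_cloud, crown, pulp, "medium")
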