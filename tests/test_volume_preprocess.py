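import warnings

import numpy as np
import pytest

from phmsr.synthetic_data import make_segmentation_phantom_volume
from phmsr.volume_preprocess import (LabelVolume, ScmParams, VolumeImage,
                                     extract_surface_cloud, hybrid_filter,
                                     scm_adaptive_params, scm_segment_slice,
                                     segment_tooth_and_pulp)


def dice(a, b):
    s = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / s if s else 0.0


class TestHybridFilter:
    def test_constant_slice_unchanged(self):
        vol = VolumeImage(np.full((3, 32, 32), 77.0), 0.25)
        out = hybrid_filter(vol)
        assert np.allclose(out.voxels, 77.0, atol=1e-6)

    def test_even_window_rejected(self):
        vol = VolumeImage(np.zeros((2, 32, 32)), 0.25)
        with pytest.raises(ValueError):
            hybrid_filter(vol, window=4)

    def test_thin_volume_rejected(self):
        vol = VolumeImage(np.zeros((2, 3, 3)), 0.25)
        with pytest.raises(ValueError):
            hybrid_filter(vol, window=5)

    def test_noise_reduced_on_step_edge(self):
        rng = np.random.default_rng(3)
        clean = np.zeros((1, 64, 64))
        clean[:, :, 32:] = 100.0
        noisy = clean + rng.normal(0, 10.0, clean.shape)
        out = hybrid_filter(VolumeImage(noisy, 0.25))
        mse_before = np.mean((noisy - clean) ** 2)
        mse_after = np.mean((out.voxels - clean) ** 2)
        assert mse_after < mse_before

    def test_range_not_expanded(self):
        rng = np.random.default_rng(4)
        vol = VolumeImage(rng.uniform(10, 200, (2, 40, 40)), 0.25)
        out = hybrid_filter(vol)
        assert out.voxels.min() >= vol.voxels.min() - 1e-6
        assert out.voxels.max() <= vol.voxels.max() + 1e-6


class TestScmAdaptiveParams:
    def test_direct_substitution(self):
        # mean 100, max 255 slice
        sl = np.full((10, 10), 100.0)
        sl[0, 0] = 255.0
        sl[0, 1] = 2 * 100.0 - 255.0  # keep the mean exactly 100
        p = scm_adaptive_params(sl, C=50.0)
        assert p.V_E == pytest.approx(200.0)
        assert p.E0 == pytest.approx(255.0)
        assert p.alpha_e == pytest.approx(0.5)

    def test_moments_match_independent_recomputation(self):
        rng = np.random.default_rng(7)
        sl = rng.uniform(1, 250, (30, 40))
        p = scm_adaptive_params(sl, C=10.0, a=0.3)
        # second code path: explicit loops over the flattened slice
        vals = [float(v) for v in sl.ravel()]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        assert p.alpha_e == pytest.approx(10.0 / mean, rel=1e-12)
        assert p.V_E == pytest.approx(2 * mean, rel=1e-12)
        assert p.beta == pytest.approx(0.3 * np.log(mean), rel=1e-12)
        assert p.alpha_u == pytest.approx(np.log(1.0 / var), rel=1e-9)
        assert p.E0 == pytest.approx(max(vals))

    def test_scale_awareness(self):
        rng = np.random.default_rng(8)
        sl = rng.uniform(10, 100, (20, 20))
        p1 = scm_adaptive_params(sl, C=5.0)
        p2 = scm_adaptive_params(2 * sl, C=5.0)
        assert p2.V_E == pytest.approx(2 * p1.V_E)
        assert p2.E0 == pytest.approx(2 * p1.E0)
        assert p2.alpha_e == pytest.approx(p1.alpha_e / 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            scm_adaptive_params(np.full((5, 5), 10.0))


class TestScmSegmentSlice:
    def test_uniform_image_single_label(self):
        sl = np.full((16, 16), 120.0)
        params = ScmParams(alpha_e=0.1, V_E=240.0, beta=0.2, alpha_u=3.0,
                           E0=121.0, C=12.0, a=0.2)
        labels, first = scm_segment_slice(sl, params)
        fired = first[first > 0]
        assert len(np.unique(fired)) == 1
        assert labels.max() == 1

    def test_disk_phantom_dice(self):
        yy, xx = np.mgrid[:64, :64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15 ** 2
        sl = np.where(mask, 200.0, 50.0)
        params = scm_adaptive_params(sl)
        labels, _ = scm_segment_slice(sl, params)
        # the disk must land in a single firing bin
        disk_label = np.bincount(labels[mask]).argmax()
        assert dice(labels == disk_label, mask) >= 0.99

    def test_noisy_disk_phantom_dice(self):
        rng = np.random.default_rng(5)
        yy, xx = np.mgrid[:64, :64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15 ** 2
        sl = np.where(mask, 200.0, 50.0) + rng.normal(0, 5.0, (64, 64))
        params = scm_adaptive_params(sl)
        labels, _ = scm_segment_slice(sl, params)
        # merge bins by majority class inside/outside
        disk_bins = [lab for lab in range(1, labels.max() + 1)
                     if mask[labels == lab].mean() > 0.5]
        pred = np.isin(labels, disk_bins)
        assert dice(pred, mask) >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        sl = rng.uniform(10, 250, (32, 32))
        params = scm_adaptive_params(sl)
        l1, f1 = scm_segment_slice(sl, params)
        l2, f2 = scm_segment_slice(sl, params)
        assert np.array_equal(l1, l2) and np.array_equal(f1, f2)


class TestSegmentToothAndPulp:
    def test_phantom_pulp_dice(self):
        vol, truth = make_segmentation_phantom_volume(noise_sigma=5.0, seed=1)
        lab = segment_tooth_and_pulp(vol)
        assert dice(lab.mask_for("tooth"), truth.mask_for("tooth")) >= 0.9
        assert lab.labels_for("pulp"), "no pulp cavity found"
        assert dice(lab.mask_for("pulp"), truth.mask_for("pulp")) >= 0.9

    def test_all_background_volume_warns(self):
        vol = VolumeImage(np.zeros((4, 16, 16)), 0.25)
        with pytest.warns(UserWarning):
            lab = segment_tooth_and_pulp(vol)
        assert lab.labels.max() == 0

    def test_two_disjoint_teeth_reported(self):
        vol, truth = make_segmentation_phantom_volume(
            shape=(40, 64, 120), noise_sigma=2.0, seed=3, n_teeth=2)
        lab = segment_tooth_and_pulp(vol)
        assert len(lab.labels_for("tooth")) == 2


@pytest.fixture(scope="module")
def ball_labels():
    zz, yy, xx = np.mgrid[:30, :30, :30]
    mask = (zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2 <= 10 ** 2
    return LabelVolume(mask.astype(int), {0: "background", 1: "tooth"}, 0.25)


class TestExtractSurfaceCloud:
    def test_ball_radius_in_mm(self, ball_labels):
        cloud = extract_surface_cloud(ball_labels, 1, smoothing_iters=2)
        center = cloud.points.mean(axis=0)
        radii = np.linalg.norm(cloud.points - center, axis=1)
        assert abs(radii.mean() - 2.5) < 0.25  # one voxel

    def test_zero_smoothing_equals_raw_marching_cubes(self, ball_labels):
        from skimage.measure import marching_cubes
        cloud = extract_surface_cloud(ball_labels, 1, smoothing_iters=0)
        verts, _, _, _ = marching_cubes(
            (ball_labels.labels == 1).astype(float), level=0.5,
            spacing=(0.25, 0.25, 0.25))
        assert np.allclose(cloud.points, verts, atol=1e-12)

    def test_smoothing_reduces_roughness_monotonically(self, ball_labels):
        from scipy.spatial import cKDTree

        def roughness(pts):
            tree = cKDTree(pts)
            _, idx = tree.query(pts, k=7)
            neigh = pts[idx[:, 1:]].mean(axis=1)
            return np.linalg.norm(pts - neigh, axis=1).mean()

        vals = [roughness(extract_surface_cloud(ball_labels, 1, i).points)
                for i in range(0, 10, 2)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_absent_label_raises(self, ball_labels):
        with pytest.raises((KeyError, ValueError)):
            extract_surface_cloud(ball_labels, 7)

    def test_normals_are_outward_unit(self, ball_labels):
        cloud = extract_surface_cloud(ball_labels, 1, smoothing_iters=2)
        assert np.allclose(np.linalg.norm(cloud.normals, axis=1), 1.0, atol=1e-6)
        center = cloud.points.mean(axis=0)
        outward = cloud.points - center
        assert np.mean(np.einsum("ij,ij->i", cloud.normals, outward) > 0) > 0.95
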