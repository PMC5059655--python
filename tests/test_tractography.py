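"""Probabilistic tracking: posteriors, propagation, connectivity, visitation."""

import numpy as np
import pytest

from dtreg import tractography as trk
from dtreg.formats_io import RoiMask, Volume
from dtreg.sphere import icosphere
from tests.conftest import single_voxel_dwi

D_BUNDLE = np.diag([1.7e-3, 0.3e-3, 0.3e-3])


class TestSphere:
    @pytest.mark.parametrize("sub,n", [(0, 12), (1, 42), (2, 162), (3, 642)])
    def test_vertex_counts(self, sub, n):
        s = icosphere(sub)
        assert len(s) == n
        np.testing.assert_allclose(np.linalg.norm(s.points, axis=1), 1.0,
                                   atol=1e-12)
        assert np.isclose(s.weights.sum(), 1.0)


class TestDirectionPosterior:
    def test_sums_to_one(self, gtab):
        sig = single_voxel_dwi(gtab, D_BUNDLE, sigma=20.0, seed=0).data[0, 0, 0]
        post = trk.direction_posterior(sig, gtab, None, icosphere(2))
        assert np.isclose(post.sum(), 1.0, atol=1e-12)

    def test_anisotropic_argmax_near_e1(self, gtab):
        # brute-force oracle: the evaluated posterior must peak within one
        # vertex spacing of the true principal axis (antipodally)
        sig = single_voxel_dwi(gtab, D_BUNDLE).data[0, 0, 0]
        sphere = icosphere(3)
        post = trk.direction_posterior(sig, gtab, None, sphere)
        peak = sphere.points[np.argmax(post)]
        # coarsest vertex spacing at 642 points is ~4.4 degrees
        assert abs(peak @ [1, 0, 0]) > np.cos(np.deg2rad(5.0))

    def test_prior_confines_to_forward_hemisphere(self, gtab):
        sig = single_voxel_dwi(gtab, 1e-3 * np.eye(3)).data[0, 0, 0]
        sphere = icosphere(2)
        prev = np.array([0.0, 0.0, 1.0])
        post = trk.direction_posterior(sig, gtab, prev, sphere)
        behind = sphere.points @ prev <= 0
        assert post[behind].sum() == 0.0
        assert np.isclose(post.sum(), 1.0)

    def test_small_sphere_rejected(self, gtab):
        sig = single_voxel_dwi(gtab, D_BUNDLE).data[0, 0, 0]
        with pytest.raises(ValueError, match="100"):
            trk.direction_posterior(sig, gtab, None, icosphere(1))


class TestPropagate:
    def test_max_steps_bounds_length(self, straight_phantom, gtab, full_mask):
        params = trk.TrackingParams(max_steps=1, bidirectional=False)
        seed = np.array([20, 20, 10]) * 2.0  # world mm, on the bundle axis
        s = trk.propagate(seed, straight_phantom["dwi"], gtab, full_mask,
                          params, rng_seed=0)
        assert len(s.points) == 2

    def test_step_length_exact(self, straight_phantom, gtab, full_mask):
        params = trk.TrackingParams(max_steps=20, bidirectional=False)
        s = trk.propagate([40.0, 40.0, 20.0], straight_phantom["dwi"], gtab,
                          full_mask, params, rng_seed=1)
        d = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        np.testing.assert_allclose(d, s.step_length, atol=1e-6)

    def test_deterministic_given_seed(self, straight_phantom, gtab, full_mask):
        params = trk.TrackingParams(max_steps=50)
        a = trk.propagate([40.0, 40.0, 20.0], straight_phantom["dwi"], gtab,
                          full_mask, params, rng_seed=9)
        b = trk.propagate([40.0, 40.0, 20.0], straight_phantom["dwi"], gtab,
                          full_mask, params, rng_seed=9)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.terminated_reason == b.terminated_reason

    def test_seed_outside_mask_raises(self, straight_phantom, gtab):
        mask = RoiMask(np.zeros(straight_phantom["dwi"].shape3, bool))
        with pytest.raises(ValueError, match="outside"):
            trk.propagate([40.0, 40.0, 20.0], straight_phantom["dwi"], gtab,
                          mask)

    def test_follows_straight_bundle(self, straight_phantom, gtab, full_mask):
        # phantom geometry oracle: noise-free tracking stays near the axis
        s = trk.propagate([40.0, 40.0, 20.0], straight_phantom["dwi"], gtab,
                          full_mask, trk.TrackingParams(), rng_seed=2)
        vox = s.points / 2.0
        lateral = np.abs(vox[:, 1:] - [20.0, 10.0]).max()
        assert lateral < 2.0  # voxels off the centerline
        assert vox[:, 0].max() > 33 and vox[:, 0].min() < 6


class TestConnectivity:
    def test_straight_bundle_high_probability(self, straight_phantom, gtab,
                                              full_mask):
        shape = straight_phantom["dwi"].shape3
        # seed the tract core, avoiding the partial-volume shell of the tube
        yy, zz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]),
                             indexing="ij")
        core = ((yy - 20) ** 2 + (zz - 10) ** 2) <= 2.5**2
        A = np.zeros(shape, bool)
        A[2:5, core] = True
        B = np.zeros(shape, bool)
        B[35:] = True
        est, sset = trk.connectivity(RoiMask(A, "A"), RoiMask(B, "B"),
                                     straight_phantom["dwi"], gtab, full_mask,
                                     n_samples=300, rng_seed=5)
        assert est.probability >= 0.95
        assert est.n_hit <= est.n_total
        assert est.probability == est.n_hit / est.n_total

    def test_unreachable_target_probability_zero(self, straight_phantom, gtab):
        shape = straight_phantom["dwi"].shape3
        bundle = straight_phantom["bundle"].data
        A = np.zeros(shape, bool)
        A[2:5] = bundle[2:5]
        B = np.zeros(shape, bool)
        B[38:] = True
        # a zero-signal gap: every path terminates before reaching B
        gap_mask = np.ones(shape, bool)
        gap_mask[30:] = False
        est, _ = trk.connectivity(RoiMask(A, "A"), RoiMask(B, "B"),
                                  straight_phantom["dwi"], gtab,
                                  RoiMask(gap_mask), n_samples=50, rng_seed=1)
        assert est.probability == 0.0

    def test_empty_mask_raises(self, straight_phantom, gtab, full_mask):
        empty = RoiMask(np.zeros(straight_phantom["dwi"].shape3, bool))
        with pytest.raises(ValueError, match="nonempty"):
            trk.connectivity(empty, full_mask, straight_phantom["dwi"], gtab,
                             full_mask, n_samples=10)

    def test_run_is_seed_deterministic(self, straight_phantom, gtab, full_mask):
        shape = straight_phantom["dwi"].shape3
        A = RoiMask(straight_phantom["bundle"].data & (np.arange(shape[0])[:, None, None] < 6), "A")
        B = np.zeros(shape, bool)
        B[-1, -1, -1] = True
        B = RoiMask(B, "B")
        kw = dict(n_samples=20, rng_seed=42)
        est1, s1 = trk.connectivity(A, B, straight_phantom["dwi"], gtab, full_mask, **kw)
        est2, s2 = trk.connectivity(A, B, straight_phantom["dwi"], gtab, full_mask, **kw)
        assert est1.n_hit == est2.n_hit
        for a, b in zip(s1.streamlines, s2.streamlines):
            np.testing.assert_array_equal(a.points, b.points)


class TestVisitation:
    def test_single_line_counts_once(self):
        grid = Volume(np.zeros((10, 5, 5)))
        pts = np.stack([np.arange(10.0), np.full(10, 2.0), np.full(10, 2.0)],
                       axis=1)
        vis = trk.visitation_map([pts], grid)
        assert vis.data.sum() == 10
        assert np.all(vis.data[:, 2, 2] == 1)

    def test_duplicate_streamline_doubles(self):
        grid = Volume(np.zeros((10, 5, 5)))
        pts = np.stack([np.arange(10.0), np.full(10, 2.0), np.full(10, 2.0)],
                       axis=1)
        vis = trk.visitation_map([pts, pts], grid)
        assert np.all(vis.data[:, 2, 2] == 2)

    def test_total_equals_sum_of_distinct_voxels(self):
        # brute-force recount oracle on random walks
        rng = np.random.default_rng(0)
        grid = Volume(np.zeros((12, 12, 12)))
        sls, total = [], 0
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 0.7, size=(30, 3)), axis=0) + 6.0
            sls.append(pts)
            vox = np.rint(pts).astype(int)
            ok = np.all((vox >= 0) & (vox < 12), axis=1)
            total += len(np.unique(vox[ok], axis=0))
        vis = trk.visitation_map(sls, grid)
        assert vis.data.sum() == total
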