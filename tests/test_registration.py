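"""Symmetric diffeomorphic registration and tensor reorientation."""

import numpy as np
import pytest
from scipy import ndimage

from dtreg import phantom as ph
from dtreg import registration as reg
from dtreg.formats_io import RoiMask, Volume
from dtreg.tensor_model import (
    TensorField,
    coeffs_from_tensors,
    eigendecompose,
    fa_map,
)


@pytest.fixture(scope="module")
def smooth_image():
    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.normal(size=(40, 40, 20)), 2.5)


@pytest.fixture(scope="module")
def known_warp():
    return ph.make_ground_truth_warp((40, 40, 20), 3.0, seed=5)


class TestAffineInit:
    def test_identical_inputs_identity(self, smooth_image):
        M = reg.affine_initialize(Volume(smooth_image), Volume(smooth_image))
        np.testing.assert_allclose(M, np.eye(4), atol=1e-12)

    def test_translation_recovery(self, smooth_image):
        moving = Volume(ndimage.shift(smooth_image, (3, 0, 0), order=1))
        M = reg.affine_initialize(moving, Volume(smooth_image))
        assert np.abs(M[:3, 3] - [3, 0, 0]).max() < 0.2

    def test_rotation_recovery(self, smooth_image):
        rot = ndimage.rotate(smooth_image, 5.0, axes=(0, 1), reshape=False,
                             order=1)
        M = reg.affine_initialize(Volume(rot), Volume(smooth_image))
        A = M[:3, :3] / np.cbrt(np.linalg.det(M[:3, :3]))
        angle = np.degrees(np.arctan2(A[1, 0], A[0, 0]))
        assert abs(abs(angle) - 5.0) < 0.5

    def test_empty_input_raises(self, smooth_image):
        with pytest.raises(ValueError, match="empty"):
            reg.affine_initialize(Volume(np.zeros((8, 8, 8))),
                                  Volume(smooth_image[:8, :8, :8]))


class TestLocalCC:
    def test_self_similarity_is_one(self, smooth_image):
        sim, _ = reg.local_cross_correlation(smooth_image, smooth_image, 2)
        assert np.isclose(sim, 1.0, atol=1e-9)

    def test_affine_intensity_invariance(self, smooth_image):
        sim, _ = reg.local_cross_correlation(smooth_image,
                                             2.0 * smooth_image + 5.0, 2)
        assert np.isclose(sim, 1.0, atol=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(30, 30, 15))
        b = rng.normal(size=(30, 30, 15))
        sim, _ = reg.local_cross_correlation(a, b, 2)
        assert abs(sim) < 0.05

    def test_zero_variance_window_contributes_zero(self):
        a = np.zeros((10, 10, 10))
        b = np.zeros((10, 10, 10))
        b[5, 5, 5] = 1.0
        sim, force = reg.local_cross_correlation(a, b, 2)
        assert np.isfinite(sim) and np.all(np.isfinite(force))


class TestVelocityIntegration:
    def test_zero_velocity_identity(self):
        vf = reg.VelocityField(np.zeros((10, 10, 10, 3)))
        d = reg.integrate_velocity(vf, 0.0, 1.0)
        assert np.all(d.displacement == 0)

    def test_constant_velocity_translation(self):
        v = np.zeros((16, 16, 16, 3))
        v[..., 0] = 0.2
        d = reg.integrate_velocity(reg.VelocityField(v), 0.0, 0.5)
        interior = d.displacement[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(interior[..., 0], 0.1, atol=1e-6)

    def test_forward_backward_compose_to_identity(self, known_warp):
        v = known_warp.displacement  # treat as a stationary velocity
        fwd = reg.integrate_velocity(reg.VelocityField(v), 0.0, 1.0)
        comp = reg.compose_displacements(fwd.inverse_displacement,
                                         fwd.displacement)
        res = np.linalg.norm(comp, axis=-1)
        assert res.max() < 0.05

    def test_nonfinite_velocity_rejected(self):
        v = np.zeros((4, 4, 4, 3))
        v[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            reg.VelocityField(v)


class TestWarpScalar:
    def test_identity_unchanged(self, smooth_image):
        d = reg.DeformationField(np.zeros(smooth_image.shape + (3,)))
        out = reg.warp_scalar(Volume(smooth_image), d)
        np.testing.assert_array_equal(out.data, smooth_image)

    def test_integer_translation_exact(self, smooth_image):
        disp = np.zeros(smooth_image.shape + (3,))
        disp[..., 0] = 2.0
        out = reg.warp_scalar(Volume(smooth_image),
                              reg.DeformationField(disp))
        np.testing.assert_allclose(out.data[:-2], smooth_image[2:], atol=1e-12)

    def test_warp_unwarp_roundtrip(self, smooth_image, known_warp):
        d = known_warp.as_deformation()
        warped = reg.warp_scalar(Volume(smooth_image), d)
        back = reg.warp_scalar(
            warped, reg.DeformationField(known_warp.inverse_displacement))
        dyn = smooth_image.max() - smooth_image.min()
        core = (slice(4, -4),) * 3
        err = np.abs(back.data[core] - smooth_image[core]).max()
        assert err < 0.05 * dyn


class TestSynRegister:
    def test_self_registration_near_identity(self, smooth_image):
        res = reg.syn_register(Volume(smooth_image), Volume(smooth_image))
        mean_disp = np.linalg.norm(res.full_forward.displacement,
                                   axis=-1).mean()
        assert mean_disp < 0.05

    def test_known_warp_recovery(self, smooth_image, known_warp):
        moving = Volume(reg.warp_displacement(smooth_image,
                                              known_warp.displacement))
        res = reg.syn_register(moving, Volume(smooth_image))
        err = np.linalg.norm(
            res.full_forward.displacement - known_warp.inverse_displacement,
            axis=-1)
        assert err.mean() < 1.0

    def test_inverse_consistency(self, smooth_image, known_warp):
        moving = Volume(reg.warp_displacement(smooth_image,
                                              known_warp.displacement))
        res = reg.syn_register(moving, Volume(smooth_image))
        comp = reg.compose_displacements(
            res.full_forward.displacement,
            res.full_forward.inverse_displacement)
        r = np.linalg.norm(comp, axis=-1)
        assert r.mean() < 0.1
        assert np.percentile(r, 95) < 0.25

    def test_swap_yields_mutual_inverses(self, smooth_image, known_warp):
        moving = Volume(reg.warp_displacement(smooth_image,
                                              known_warp.displacement))
        fixed = Volume(smooth_image)
        ab = reg.syn_register(moving, fixed)
        ba = reg.syn_register(fixed, moving)
        comp = reg.compose_displacements(ba.full_forward.displacement,
                                         ab.full_forward.displacement)
        assert np.linalg.norm(comp, axis=-1).mean() < 0.2

    def test_ssd_metric_also_recovers(self, smooth_image):
        warp = ph.make_ground_truth_warp((40, 40, 20), 2.0, seed=9)
        moving = Volume(reg.warp_displacement(smooth_image, warp.displacement))
        res = reg.syn_register(moving, Volume(smooth_image),
                               reg.RegistrationParams(metric="ssd"))
        err = np.linalg.norm(
            res.full_forward.displacement - warp.inverse_displacement, axis=-1)
        assert err.mean() < 1.0

    def test_grid_mismatch_raises(self, smooth_image):
        with pytest.raises(ValueError, match="grid"):
            reg.syn_register(Volume(smooth_image[:20]), Volume(smooth_image))


class TestWarpTensors:
    def _field_from_tensors(self, tensors):
        shape = tensors.shape[:3]
        return TensorField(
            coeffs=coeffs_from_tensors(tensors), s0=np.full(shape, 1000.0),
            mask=RoiMask(np.ones(shape, bool)), design=np.empty((0, 7)),
        )

    def test_identity_deformation_unchanged(self, default_phantom):
        tf = default_phantom["tf_true"]
        d = reg.DeformationField(np.zeros(tf.shape3 + (3,)))
        out = reg.warp_tensor_field(tf, d)
        np.testing.assert_allclose(out.coeffs, tf.coeffs, atol=1e-15)

    def test_global_rotation_conjugates_tensors(self):
        # conjugation-invariance oracle: a rigid rotation warp must rotate
        # every tensor by the same R and leave FA untouched
        ang = np.deg2rad(7.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        shape = (24, 24, 12)
        D0 = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        tensors = np.broadcast_to(D0, shape + (3, 3)).copy()
        tf = self._field_from_tensors(tensors)
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                    indexing="ij"), axis=-1)
        c = (np.array(shape) - 1) / 2
        disp = (grid - c) @ R.T + c - grid  # pull-back: x -> R(x-c)+c
        out = reg.warp_tensor_field(tf, reg.DeformationField(disp))
        core = out.coeffs[8:-8, 8:-8, 4:-4]
        from dtreg.tensor_model import tensors_from_coeffs

        expect = R.T @ D0 @ R  # pull-back by R rotates content by R^-1
        got = tensors_from_coeffs(core).reshape(-1, 3, 3)
        np.testing.assert_allclose(got, np.broadcast_to(expect, got.shape),
                                   atol=2e-5 * D0.max())
        ef = eigendecompose(out)
        fa_core = fa_map(ef).data[8:-8, 8:-8, 4:-4]
        assert np.allclose(fa_core, fa_map(eigendecompose(tf)).data[0, 0, 0],
                           atol=1e-3)

    def test_pure_scaling_keeps_fa(self):
        # polar-decomposition oracle: anisotropic scaling has identity
        # rotation part, so FA must not change
        shape = (20, 20, 12)
        D0 = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        tf = self._field_from_tensors(np.broadcast_to(D0, shape + (3, 3)).copy())
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                    indexing="ij"), axis=-1)
        c = (np.array(shape) - 1) / 2
        S = np.diag([1.1, 0.9, 1.0])
        disp = (grid - c) @ S.T + c - grid
        out = reg.warp_tensor_field(tf, reg.DeformationField(disp))
        ef = eigendecompose(out)
        fa0 = fa_map(eigendecompose(tf)).data[0, 0, 0]
        core = fa_map(ef).data[6:-6, 6:-6, 4:-4]
        assert np.abs(core - fa0).max() < 1e-6

    def test_reorientation_preserves_spectrum(self, default_phantom):
        # rotation conjugation preserves eigenvalues exactly: compare the
        # warped field's spectrum with the resampled-without-reorientation one
        tf = default_phantom["tf_true"]
        warp = ph.make_ground_truth_warp(tf.shape3, 2.0, seed=3)
        out = reg.warp_tensor_field(tf, warp.as_deformation())
        resampled = np.stack(
            [reg.warp_displacement(tf.coeffs[..., c], warp.displacement)
             for c in range(6)], axis=-1)
        from dtreg.tensor_model import eigendecompose_tensors, tensors_from_coeffs

        lam_reor = eigendecompose_tensors(tensors_from_coeffs(out.coeffs)).lambdas
        lam_plain = eigendecompose_tensors(tensors_from_coeffs(resampled)).lambdas
        np.testing.assert_allclose(lam_reor, lam_plain, atol=1e-12)
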