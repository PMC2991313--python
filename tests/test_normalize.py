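"""Gaussian smoothing, affine and B-spline registration, warping."""

import numpy as np
import pytest

from autorad3d.core import Volume
from autorad3d.errors import InvalidGridError
from autorad3d.normalize import (
    FWHM_TO_SIGMA,
    _default_grid_spacing,
    register_affine_3d,
    register_bspline_3d,
    smooth_gaussian,
    smooth_template,
    warp,
)
from autorad3d.phantom import PhantomSpec, make_phantom_volume
from autorad3d.transforms import AffineTransform3D, BSplineTransform3D

VOX = np.array([10.0, 10.0, 20.0])


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self, phantom_volume):
        out = smooth_gaussian(phantom_volume, 0.0)
        assert np.array_equal(out.voxels, phantom_volume.voxels)

    def test_fwhm_sigma_relation(self):
        assert 30.0 * FWHM_TO_SIGMA == pytest.approx(12.7398, abs=1e-3)

    def test_interior_blob_mass_preserved(self):
        # oracle: direct summation; Gaussian preserves mass away from edges
        vox = np.zeros((40, 40, 20))
        vox[18:22, 18:22, 8:12] = 100.0
        mask = np.ones_like(vox, bool)
        vol = Volume(vox, tuple(VOX), mask=mask)
        sm = smooth_gaussian(vol, 3.0 * VOX)
        assert sm.voxels.sum() == pytest.approx(vox.sum(), rel=1e-3)

    def test_mask_aware_no_background_bleed(self, phantom_volume):
        sm = smooth_gaussian(phantom_volume, 3.0 * VOX)
        assert np.all(sm.voxels[~phantom_volume.mask] == 0)
        inside = phantom_volume.mask
        # normalized convolution keeps in-mask values in the value range
        assert sm.voxels[inside].min() >= phantom_volume.voxels[inside].min() - 1e-6

    def test_template_smoothing_uses_three_voxel_fwhm(self, phantom_volume):
        a = smooth_template(phantom_volume, 3.0)
        b = smooth_gaussian(phantom_volume, 3.0 * VOX)
        assert np.array_equal(a.voxels, b.voxels)


class TestWarp:
    def test_identity_warp_is_exact(self, phantom_volume):
        out = warp(phantom_volume, None, None, phantom_volume)
        assert np.allclose(out.voxels, phantom_volume.voxels, atol=1e-12)

    def test_integer_voxel_translation_is_exact(self, phantom_volume):
        t = AffineTransform3D(np.eye(3), np.array([10.0, 0.0, 0.0]),
                              phantom_volume.physical_center())
        out = warp(phantom_volume, t, None, phantom_volume)
        # out(i) = in(i+1) along x, exact under linear interpolation
        assert np.allclose(out.voxels[:-1], phantom_volume.voxels[1:], atol=1e-12)

    def test_warp_inverse_warp_round_trip(self, phantom_volume):
        from scipy import ndimage

        center = phantom_volume.physical_center()
        t = AffineTransform3D.from_params(
            [15, -25, 10, 2, -1, 3, 1.05, 0.97, 1.02, 0, 0, 0], center
        )
        fwd = warp(phantom_volume, t, None, phantom_volume, order=3)
        back = warp(fwd, t.inverse(), None, phantom_volume, order=3)
        interior = ndimage.binary_erosion(phantom_volume.mask, iterations=3)
        rng_dyn = phantom_volume.voxels.max() - phantom_volume.voxels.min()
        rms = np.sqrt(np.mean((back.voxels - phantom_volume.voxels)[interior] ** 2))
        assert rms < 0.01 * rng_dyn

    def test_zero_bspline_composes_to_pure_affine(self, phantom_volume):
        center = phantom_volume.physical_center()
        t = AffineTransform3D.from_params(
            [30, 0, 0, 0, 0, 5, 1.1, 1.0, 1.0, 0, 0, 0], center
        )
        zero = BSplineTransform3D.zeros_covering(
            (0, 0, 0),
            (np.array(phantom_volume.shape) - 1) * VOX,
            _default_grid_spacing(phantom_volume),
        )
        a = warp(phantom_volume, t, None, phantom_volume)
        b = warp(phantom_volume, t, zero, phantom_volume)
        assert np.allclose(a.voxels, b.voxels, atol=1e-9)


class TestRegisterAffine3D:
    def test_self_registration_identity(self, phantom_volume):
        t = register_affine_3d(phantom_volume, phantom_volume)
        assert np.abs(t.matrix - np.eye(3)).max() < 1e-3
        assert np.all(np.abs(t.translation / VOX) < 0.5)

    def test_isotropic_scale_recovered_within_one_percent(self, small_spec,
                                                          phantom_volume):
        center = phantom_volume.physical_center()
        a = AffineTransform3D.from_params(
            [0, 0, 0, 0, 0, 0, 1.10, 1.10, 1.10, 0, 0, 0], center
        )
        moving = make_phantom_volume(small_spec, affine=a)
        t = register_affine_3d(phantom_volume, moving)
        d = a.compose(t).decompose()  # identity if exactly recovered
        assert np.all(np.abs(d["scales"] - 1.0) < 0.01)

    def test_translation_recovered_within_half_voxel(self, small_spec,
                                                     phantom_volume):
        center = phantom_volume.physical_center()
        a = AffineTransform3D.from_params(
            [50, -30, 20, 0, 0, 0, 1, 1, 1, 0, 0, 0], center
        )
        moving = make_phantom_volume(small_spec, affine=a)
        t = register_affine_3d(phantom_volume, moving)
        d = a.compose(t).decompose()
        assert np.all(np.abs(d["translation"] / VOX) < 0.5)


class TestRegisterBSpline3D:
    def test_identity_recovery_zero_coefficients(self, phantom_volume):
        b = register_bspline_3d(phantom_volume, phantom_volume)
        disp_vox = np.abs(b.coefficients).max(axis=(0, 1, 2)) / VOX
        assert np.all(disp_vox < 0.25)

    def test_single_bump_displacement_recovered(self, phantom_volume):
        gs = _default_grid_spacing(phantom_volume)
        truth = BSplineTransform3D.zeros_covering(
            np.zeros(3), (np.array(phantom_volume.shape) - 1) * VOX, gs
        )
        ci = np.array(truth.coefficients.shape[:3]) // 2
        truth.coefficients[ci[0], ci[1], ci[2]] = [30.0, -20.0, 40.0]
        moving = warp(phantom_volume, None, truth, phantom_volume, order=3)
        rec = register_bspline_3d(phantom_volume, moving)
        d_true = truth.displacement_on_grid(phantom_volume.shape, VOX, np.zeros(3))
        d_rec = rec.displacement_on_grid(phantom_volume.shape, VOX, np.zeros(3))
        diff_vox = (d_rec - d_true) / VOX
        rms = np.sqrt((diff_vox[phantom_volume.mask] ** 2).sum(axis=-1).mean())
        assert rms < 0.5

    def test_too_fine_grid_rejected(self, phantom_volume):
        with pytest.raises(InvalidGridError):
            register_bspline_3d(phantom_volume, phantom_volume,
                                grid_spacing=(15.0, 15.0, 30.0))
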