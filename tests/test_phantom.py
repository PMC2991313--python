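"""Synthetic phantom generator: geometry, determinism, ground truth."""

import numpy as np
import pytest
from skimage import measure

from autorad3d.errors import InvalidSpecError
from autorad3d.phantom import (
    GroundTruth,
    PhantomSpec,
    make_group_study,
    make_phantom_volume,
    render_film,
    slice_and_perturb,
    structure_mask,
)
from autorad3d.transforms import resample_section


class TestMakePhantomVolume:
    def test_noiseless_two_level_histogram_is_plateaus_plus_blends(self):
        spec = PhantomSpec(
            structure_levels=(("tissue", 50.0), ("nucleus", 120.0)), noise_sd=0.0
        )
        vol = make_phantom_volume(spec)
        from scipy import ndimage

        interior = ndimage.binary_erosion(vol.mask, iterations=3)
        vals = vol.voxels[interior]
        # interior values are the two baselines plus convex blends between
        # (the soft rim profile may undershoot the tissue plateau by a hair)
        assert vals.min() >= 50.0 - 0.5
        assert vals.max() <= 120.0 + 1e-9
        assert np.isclose(vals.min(), 50.0, atol=0.5)
        assert np.isclose(vals.max(), 120.0, atol=0.5)
        # the rim rolls off toward background but never overshoots
        assert vol.voxels[vol.mask].max() <= 120.0 + 1e-9
        assert np.all(vol.voxels[~vol.mask] < 50.0)

    def test_determinism_and_seed_sensitivity(self):
        spec = PhantomSpec(noise_sd=4.0, seed=9)
        a = make_phantom_volume(spec)
        b = make_phantom_volume(spec)
        assert np.array_equal(a.voxels, b.voxels)
        c = make_phantom_volume(PhantomSpec(noise_sd=4.0, seed=10))
        assert not np.array_equal(a.voxels, c.voxels)

    def test_structure_mean_matches_baseline_within_3se(self):
        spec = PhantomSpec(noise_sd=5.0, seed=2)
        vol = make_phantom_volume(spec)
        from scipy import ndimage

        region = ndimage.binary_erosion(structure_mask(spec, 2), iterations=2)
        n = region.sum()
        baseline = spec.structure_levels[1][1]
        se = spec.noise_sd / np.sqrt(n)
        # oracle: the generated noise model is iid Gaussian on each voxel
        assert abs(vol.voxels[region].mean() - baseline) < 3 * se + 0.5

    def test_degenerate_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(grid_shape=(64, 7, 40))

    def test_duplicate_activities_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(structure_levels=(("a", 50.0), ("b", 50.0)))


class TestSliceAndPerturb:
    def test_zero_perturbation_yields_identity_and_exact_planes(self, phantom_volume):
        secs, truth = slice_and_perturb(phantom_volume, 0, 0, seed=1)
        for k, sec in enumerate(secs):
            t = truth.per_section_transforms[k]
            assert t.parameters.tolist() == [0.0, 0.0, 0.0]
            assert np.array_equal(sec.pixels, phantom_volume.voxels[:, :, k])

    def test_shift_bound_honoured(self, phantom_volume):
        _, truth = slice_and_perturb(phantom_volume, 20.0, 4.0, seed=2)
        for t in truth.per_section_transforms:
            assert abs(t.tx) <= 20.0 and abs(t.ty) <= 20.0
            assert abs(t.theta) <= 4.0

    def test_mean_drawn_angle_near_zero(self):
        # oracle: moments of U(-a, a); sd of the mean = a/sqrt(3)/sqrt(n)
        spec = PhantomSpec(grid_shape=(16, 16, 150), noise_sd=0.0)
        vol = make_phantom_volume(spec)
        _, truth = slice_and_perturb(vol, 0.0, 6.0, seed=3)
        thetas = np.array([t.theta for t in truth.per_section_transforms])
        assert len(thetas) == 150
        assert abs(thetas.mean()) < 3 * (6.0 / np.sqrt(3)) / np.sqrt(150)

    def test_recorded_inverse_recovers_original_plane(self, phantom_volume):
        secs, truth = slice_and_perturb(phantom_volume, 80, 4, seed=4)
        from scipy import ndimage

        for k in (5, 20, 34):
            t = truth.per_section_transforms[k]
            rec = resample_section(secs[k].pixels, secs[k].spacing, t.inverse(),
                                   order=3)
            interior = ndimage.binary_erosion(
                phantom_volume.mask[:, :, k], iterations=4
            )
            err = np.abs(rec - phantom_volume.voxels[:, :, k])[interior]
            assert err.mean() < 1.0  # interpolation tolerance, nCi/g


class TestRenderFilm:
    def test_dust_rate_one_adds_disjoint_bright_components(self, phantom_volume):
        secs, truth = slice_and_perturb(phantom_volume, 0, 0, seed=5)
        film = render_film(secs, truth, dust_rate=1.0, seed=5)
        n_multi = 0
        for sec in film.sections:
            fg = sec.pixels > 30
            if measure.label(fg, connectivity=2).max() >= 2:
                n_multi += 1
        assert n_multi >= int(0.9 * len(film.sections))

    def test_quantization_error_bound(self, phantom_volume):
        from autorad3d.calibrate import fit_calibration

        secs, truth = slice_and_perturb(phantom_volume, 0, 0, seed=6)
        film = render_film(secs, truth, seed=6)
        curve = fit_calibration(film.standards)
        g = np.linspace(*curve.valid_range, 4000)
        bound = np.max(np.gradient(curve(g), g)) * 0.5 + 1e-9
        k = 20
        recovered = curve(film.sections[k].pixels.astype(float))
        assert np.abs(recovered - secs[k].pixels).max() <= bound

    def test_out_of_range_activities_clamped_and_counted(self, phantom_volume):
        secs, truth = slice_and_perturb(phantom_volume, 0, 0, seed=7)
        hot = secs[20].copy()
        hot.pixels[30, 30] = 999.0  # beyond the standards range
        film = render_film([hot], truth, seed=7)
        assert film.clamp_counts[0] >= 1
        assert film.sections[0].pixels.dtype == np.uint8


class TestMakeGroupStudy:
    def test_subject_count_and_groups(self):
        spec = PhantomSpec(grid_shape=(32, 32, 10), noise_sd=2.0)
        study = make_group_study(spec, n_per_group=8, effect_size=0.1, seed=1,
                                 max_shift=0, max_angle=0)
        assert len(study.subjects) == 16
        assert sum(s.group == "A" for s in study.subjects) == 8

    def test_effect_size_reflected_in_region_means(self):
        spec = PhantomSpec(noise_sd=2.0)
        study = make_group_study(spec, n_per_group=6, effect_size=0.10, seed=3,
                                 max_shift=0, max_angle=0)
        region = study.activation_mask
        mean_a = np.mean([s.volume.voxels[region].mean()
                          for s in study.subjects if s.group == "A"])
        mean_b = np.mean([s.volume.voxels[region].mean()
                          for s in study.subjects if s.group == "B"])
        # oracle: direct means over the generated volumes
        assert mean_b / mean_a == pytest.approx(1.10, abs=0.03)

    def test_null_groups_are_exchangeable_draws(self):
        spec = PhantomSpec(noise_sd=2.0, grid_shape=(32, 32, 10))
        study = make_group_study(spec, n_per_group=4, effect_size=0.0, seed=4,
                                 max_shift=0, max_angle=0)
        means = {g: np.mean([s.volume.voxels[s.volume.mask].mean()
                             for s in study.subjects if s.group == g])
                 for g in "AB"}
        assert means["B"] / means["A"] == pytest.approx(1.0, abs=0.05)


def test_ground_truth_requires_monotone_calibration_pairs():
    with pytest.raises(InvalidSpecError):
        GroundTruth(calibration_pairs=np.array([[0, 0], [10, 5], [20, 4], [30, 9]]))
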