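"""Reorientation, reslicing, bias correction, segmentation, extents."""

import numpy as np
import pytest
from scipy import ndimage

from tmplkit.core_io import ValidationError, Volume, default_affine
from tmplkit.phantoms import PhantomSpec, generate_subject
from tmplkit.preprocess import (DegenerateMixtureError, bias_correct, measure_extent,
                                reorient_principal_axes, resample_isotropic,
                                segment_tissues)

from conftest import ellipsoid_volume


def _mask_volume(base, threshold=0.1):
    return Volume((base.values > threshold).astype(float), base.spacing,
                  base.affine, "probability")


class TestReorient:
    def test_axis_aligned_ellipsoid_keeps_identity(self):
        vol = ellipsoid_volume()
        _, rigid = reorient_principal_axes(vol, 0.5)
        # rotation within ~1 degree of identity
        assert np.allclose(rigid[:3, :3], np.eye(3), atol=0.02)

    def test_rotated_ellipsoid_recovers_extents(self):
        """Extents after reorientation match the unrotated analytic ellipsoid."""
        vol = ellipsoid_volume(shape=(48, 48, 48), spacing=(4.0,) * 3,
                               semi_axes_mm=(70.0, 50.0, 35.0))
        e_ref = measure_extent(vol, 0.5)
        ang = np.deg2rad(10.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0],
                      [0, 0, 1.0]])
        centre = (np.asarray(vol.shape) - 1) / 2
        rotated = ndimage.affine_transform(vol.values, R, offset=centre - R @ centre,
                                           order=1)
        re, _ = reorient_principal_axes(Volume(rotated, vol.spacing, vol.affine), 0.5)
        e = measure_extent(re, 0.5)
        for got, want in ((e.length_mm, e_ref.length_mm), (e.width_mm, e_ref.width_mm),
                          (e.height_mm, e_ref.height_mm)):
            assert abs(got - want) <= vol.spacing[0]

    def test_sphere_degenerates_to_identity_with_warning(self, caplog):
        vol = ellipsoid_volume(semi_axes_mm=(60.0, 60.0, 60.0))
        with caplog.at_level("WARNING"):
            _, rigid = reorient_principal_axes(vol, 0.5)
        assert np.allclose(rigid[:3, :3], np.eye(3))
        assert any("degenerate" in r.message for r in caplog.records)

    def test_empty_mask_raises(self):
        vol = ellipsoid_volume()
        with pytest.raises(ValidationError):
            reorient_principal_axes(vol, 10.0)


class TestResampleIsotropic:
    def test_anisotropic_to_isotropic_preserves_world_extent(self):
        sh = (32, 64, 64)
        spacing = (1.0, 0.5, 0.5)
        idx = np.indices(sh, dtype=float)
        centre = (np.asarray(sh) - 1) / 2
        r2 = sum(((idx[a] - centre[a]) * spacing[a] / 10.0) ** 2 for a in range(3))
        vol = Volume((r2 <= 1.0).astype(float), spacing, default_affine(spacing, sh))
        out = resample_isotropic(vol, 1.0)
        assert out.spacing == (1.0, 1.0, 1.0)
        e_in = measure_extent(vol, 0.5)
        e_out = measure_extent(out, 0.5)
        assert abs(e_in.length_mm - e_out.length_mm) <= 1.0
        assert abs(e_in.width_mm - e_out.width_mm) <= 1.0

    def test_identity_resample_is_exact(self, rng):
        vol = Volume(rng.random((16, 16, 16)), (2.0,) * 3,
                     default_affine((2.0,) * 3, (16,) * 3))
        out = resample_isotropic(vol, 2.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_constant_volume_preserved_under_linear_interp(self):
        vol = Volume(np.full((16, 16, 16), 7.5), (3.0,) * 3,
                     default_affine((3.0,) * 3, (16,) * 3))
        out = resample_isotropic(vol, 2.0)
        np.testing.assert_allclose(out.values[1:-1, 1:-1, 1:-1], 7.5, atol=1e-9)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValidationError):
            resample_isotropic(ellipsoid_volume(), 0.0)


class TestBiasCorrect:
    def test_recovers_clean_image_under_known_bias(self):
        """Degree-2 bias of amplitude 0.2 is removed almost completely."""
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=6.0,
                           strata=[("a", 1, 1)], warp_sd_mm=0.0, noise_sd=0.0,
                           bias_amplitude=0.2)
        s = generate_subject(spec, "a", "F", 1)
        mask = _mask_volume(s.clean_t1)
        corrected, bias = bias_correct(s.t1, mask, degree=2)
        m = mask.values > 0.5
        r = np.corrcoef(corrected.values[m], s.clean_t1.values[m])[0, 1]
        assert r > 0.99
        # identity vol = corrected * bias holds everywhere
        np.testing.assert_allclose(corrected.values * bias.values, s.t1.values,
                                   rtol=1e-10)
        # mask mean preserved
        assert abs(corrected.values[m].mean() / s.t1.values[m].mean() - 1) < 1e-3

    def test_bias_free_input_nearly_unchanged(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=6.0,
                           strata=[("a", 1, 1)], warp_sd_mm=0.0, noise_sd=0.0,
                           bias_amplitude=0.0)
        s = generate_subject(spec, "a", "F", 1)
        mask = _mask_volume(s.t1)
        corrected, _ = bias_correct(s.t1, mask, degree=2)
        m = mask.values > 0.5
        rms = np.sqrt(((corrected.values[m] - s.t1.values[m]) ** 2).mean())
        assert rms / s.t1.values[m].mean() < 0.01

    def test_idempotent_within_half_percent(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=6.0,
                           strata=[("a", 1, 1)], warp_sd_mm=0.0, noise_sd=0.0,
                           bias_amplitude=0.2)
        s = generate_subject(spec, "a", "F", 2)
        mask = _mask_volume(s.clean_t1)
        once, _ = bias_correct(s.t1, mask, degree=2)
        twice, _ = bias_correct(once, mask, degree=2)
        m = mask.values > 0.5
        rms = np.sqrt(((twice.values[m] - once.values[m]) ** 2).mean())
        assert rms / once.values[m].mean() < 0.005

    def test_nonpositive_intensities_rejected(self):
        vol = ellipsoid_volume()  # zeros inside nothing, but mask covers zeros
        mask = Volume(np.ones(vol.shape), vol.spacing, vol.affine, "probability")
        with pytest.raises(ValidationError):
            bias_correct(vol, mask)


class TestSegmentTissues:
    def test_noiseless_phantom_recovers_true_maps(self, clean_tiny_spec):
        """Dice > 0.99 against the generator's true tissue maps at 0.3/0.6/0.9."""
        s = generate_subject(clean_tiny_spec, "60-64", "F", 3)
        mask = _mask_volume(s.t1)
        tm = segment_tissues(s.t1, mask, n_classes=3, seed=0)
        for est, truth in zip(tm.maps, s.tissues.maps):
            a = est.values > 0.5
            b = truth.values > 0.5
            dice = 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)
            assert dice > 0.99

    def test_probabilities_sum_to_one(self, tiny_spec):
        s = generate_subject(tiny_spec, "60-64", "M", 4)
        mask = _mask_volume(s.clean_t1)
        tm = segment_tissues(s.t1, mask, n_classes=3, seed=1)
        total = sum(m.values for m in tm.maps) + tm.background.values
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_seed_stability_when_classes_separated(self, clean_tiny_spec):
        s = generate_subject(clean_tiny_spec, "60-64", "F", 5)
        mask = _mask_volume(s.t1)
        t1maps = segment_tissues(s.t1, mask, 3, seed=0)
        t2maps = segment_tissues(s.t1, mask, 3, seed=99)
        for m1, m2 in zip(t1maps.maps, t2maps.maps):
            a, b = m1.values > 0.5, m2.values > 0.5
            dice = 2 * (a & b).sum() / max(a.sum() + b.sum(), 1)
            assert dice > 0.99

    def test_constant_image_degenerate(self):
        vol = Volume(np.ones((12, 12, 12)), (2.0,) * 3,
                     default_affine((2.0,) * 3, (12,) * 3))
        mask = Volume(np.ones(vol.shape), vol.spacing, vol.affine, "probability")
        with pytest.raises(DegenerateMixtureError):
            segment_tissues(vol, mask, 3, 0)


class TestMeasureExtent:
    def test_analytic_ellipsoid_extents_and_ratio(self):
        vol = ellipsoid_volume(shape=(192, 160, 128), spacing=(1.0,) * 3,
                               semi_axes_mm=(81.0, 66.0, 50.0))
        e = measure_extent(vol, 0.5)
        assert abs(e.length_mm - 162.0) <= 1.0
        assert abs(e.width_mm - 132.0) <= 1.0
        assert abs(e.height_mm - 100.0) <= 1.0
        assert abs(e.wl_ratio - 0.815) < 0.01

    def test_single_voxel_extent_is_spacing(self):
        vals = np.zeros((8, 8, 8))
        vals[3, 4, 5] = 1.0
        vol = Volume(vals, (2.5,) * 3, default_affine((2.5,) * 3, (8,) * 3))
        e = measure_extent(vol, 0.5)
        assert e.length_mm == e.width_mm == e.height_mm == 2.5

    def test_matches_bruteforce_bounding_box(self, rng):
        vals = (rng.random((20, 20, 20)) > 0.7).astype(float)
        vol = Volume(vals, (1.5,) * 3, default_affine((1.5,) * 3, (20,) * 3))
        e = measure_extent(vol, 0.5)
        nz = np.argwhere(vals > 0.5)
        ext = (nz.max(axis=0) - nz.min(axis=0) + 1) * 1.5
        assert (e.length_mm, e.width_mm, e.height_mm) == tuple(ext)

    def test_translation_invariance(self):
        vals = np.zeros((24, 24, 24))
        vals[4:10, 6:14, 8:12] = 1.0
        vol = Volume(vals, (2.0,) * 3, default_affine((2.0,) * 3, (24,) * 3))
        shifted = Volume(np.roll(vals, (3, -2, 4), axis=(0, 1, 2)), vol.spacing,
                         vol.affine)
        e1, e2 = measure_extent(vol, 0.5), measure_extent(shifted, 0.5)
        assert (e1.length_mm, e1.width_mm, e1.height_mm) == \
               (e2.length_mm, e2.width_mm, e2.height_mm)

    def test_finer_resampling_preserves_extents(self):
        vol = ellipsoid_volume(shape=(32, 32, 32), spacing=(6.0,) * 3)
        fine = resample_isotropic(vol, 3.0)
        e1, e2 = measure_extent(vol, 0.5), measure_extent(fine, 0.5)
        assert abs(e1.length_mm - e2.length_mm) <= 6.0
        assert abs(e1.height_mm - e2.height_mm) <= 6.0

    def test_ratio_invariant_holds(self):
        vol = ellipsoid_volume()
        e = measure_extent(vol, 0.5)
        assert abs(e.wl_ratio - e.width_mm / e.length_mm) < 1e-9
        assert abs(e.hl_ratio - e.height_mm / e.length_mm) < 1e-9
        assert abs(e.hw_ratio - e.height_mm / e.width_mm) < 1e-9
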