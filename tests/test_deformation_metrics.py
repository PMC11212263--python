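"""Displacement maps, Jacobian determinants and atlas region summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmplkit.core_io import LabelAtlas, ValidationError, Volume, default_affine
from tmplkit.deformation_metrics import (abs_log_jacobian, displacement_map,
                                         jacobian_map, region_summary,
                                         to_common_space)
from tmplkit.registration import DeformationField, compose, exp_velocity, warp

from conftest import smooth_velocity

SP = (1.0, 1.0, 1.0)
SH = (24, 24, 24)


def _field(u):
    return DeformationField(u, SP, default_affine(SP, u.shape[1:]))


class TestDisplacementMap:
    def test_identity_is_zero(self):
        assert displacement_map(_field(np.zeros((3,) + SH))).values.max() == 0.0

    def test_three_four_translation_gives_five_mm(self):
        u = np.zeros((3,) + SH)
        u[0], u[1] = 3.0, 4.0
        np.testing.assert_allclose(displacement_map(_field(u)).values, 5.0)

    def test_matches_bruteforce_norm_with_anisotropic_spacing(self, rng):
        u = rng.standard_normal((3,) + SH)
        spacing = (1.0, 2.0, 0.5)
        d = DeformationField(u, spacing, default_affine(spacing, SH))
        expected = np.sqrt((u[0] * 1.0) ** 2 + (u[1] * 2.0) ** 2 + (u[2] * 0.5) ** 2)
        np.testing.assert_allclose(displacement_map(d).values, expected, atol=1e-12)

    def test_whole_mask_mean_invariant_to_axis_permutation(self, rng):
        u = rng.standard_normal((3,) + SH)
        m1 = displacement_map(_field(u)).values.mean()
        perm = np.stack([u[2], u[0], u[1]]).transpose(0, 3, 1, 2)
        m2 = displacement_map(_field(perm)).values.mean()
        assert abs(m1 - m2) < 1e-12


@settings(derandomize=True, max_examples=30, deadline=None)
@given(tx=st.floats(-3, 3), ty=st.floats(-3, 3), tz=st.floats(-3, 3),
       sx=st.floats(0.1, 4.0))
def test_displacement_scaling_and_translation_properties(tx, ty, tz, sx):
    """|u| maps are translation-exact and scale linearly with voxel size."""
    sh = (8, 8, 8)
    u = np.zeros((3,) + sh)
    u[0], u[1], u[2] = tx, ty, tz
    d1 = DeformationField(u, (1.0,) * 3, default_affine((1.0,) * 3, sh))
    dsx = DeformationField(u, (sx,) * 3, default_affine((sx,) * 3, sh))
    want = np.sqrt(tx * tx + ty * ty + tz * tz)
    np.testing.assert_allclose(displacement_map(d1).values, want, atol=1e-12)
    np.testing.assert_allclose(displacement_map(dsx).values, want * sx,
                               rtol=1e-12, atol=1e-12)


class TestJacobianMap:
    def test_identity_gives_unit_determinant(self):
        jac = jacobian_map(_field(np.zeros((3,) + SH)))
        np.testing.assert_allclose(jac.values, 1.0)
        logj = jacobian_map(_field(np.zeros((3,) + SH)), log_output=True)
        np.testing.assert_allclose(logj.values, 0.0)

    def test_global_scaling_matches_cube(self):
        """x -> 1.1 x has Jacobian determinant 1.1^3 in the interior."""
        grid = np.indices(SH, dtype=float)
        centre = (np.asarray(SH) - 1) / 2
        u = 0.1 * (grid - centre[:, None, None, None])
        jac = jacobian_map(_field(u))
        np.testing.assert_allclose(jac.values[2:-2, 2:-2, 2:-2], 1.1 ** 3, atol=1e-3)

    def test_affine_fields_match_analytic_determinant(self, rng):
        """Interior det for u = (A - I) x equals det(A) for random affines."""
        grid = np.indices(SH, dtype=float)
        centre = (np.asarray(SH) - 1) / 2
        x = grid - centre[:, None, None, None]
        for _ in range(25):
            A = np.eye(3) + rng.uniform(-0.15, 0.15, (3, 3))
            if not 0.5 < np.linalg.det(A) < 2.0:
                continue
            u = np.einsum("ij,jabc->iabc", A - np.eye(3), x)
            jac = jacobian_map(_field(u))
            np.testing.assert_allclose(jac.values[1:-1, 1:-1, 1:-1],
                                       np.linalg.det(A), atol=1e-6)

    def test_multiplicativity_under_composition(self):
        """J(a o b) ~= J(a) * J(b) o a for smooth generator-scale fields."""
        a = exp_velocity(smooth_velocity(SH, SP, sigma_vox=4, max_vox=1.0, seed=1))
        b = exp_velocity(smooth_velocity(SH, SP, sigma_vox=4, max_vox=1.0, seed=2))
        lhs = jacobian_map(compose(a, b)).values
        jb_warped = warp(jacobian_map(b), a).values
        rhs = jacobian_map(a).values * jb_warped
        sl = (slice(3, -3),) * 3
        rel = np.abs(lhs[sl] - rhs[sl]) / rhs[sl]
        assert np.nanmean(rel) < 0.05

    def test_nonpositive_fraction_raises(self):
        u = np.zeros((3,) + SH)
        u[0] = -np.indices(SH, dtype=float)[0] * 1.5  # strongly folding
        with pytest.raises(ValidationError):
            jacobian_map(_field(u))

    def test_volume_change_matches_divergence_budget(self):
        """Sum of (det - 1) approximates the net volume change of the warp."""
        v = smooth_velocity(SH, SP, sigma_vox=4, max_vox=1.0, seed=3)
        d = exp_velocity(v)
        jac = jacobian_map(d)
        # det(x) integrates the source-volume of the backward map: comparing
        # against the Monte-Carlo volume of the mapped unit cube mesh
        grid = np.indices(SH, dtype=float)
        phi = grid + d.displacement
        # volume via divergence theorem surrogate: mean det over interior
        interior = (slice(2, -2),) * 3
        vol_from_det = jac.values[interior].mean()
        # oracle: differentiate phi directly with one large stencil
        J = np.zeros(SH)
        gx = [np.gradient(phi[i], axis=(0, 1, 2)) for i in range(3)]
        M = np.empty((3, 3) + SH)
        for i in range(3):
            for j in range(3):
                M[i, j] = gx[i][j]
        det = np.linalg.det(np.moveaxis(M, (0, 1), (-2, -1)))
        assert abs(vol_from_det - det[interior].mean()) / det[interior].mean() < 0.02


class TestAbsLogJacobian:
    def test_expansion_and_contraction_weighted_equally(self):
        vals = np.full(SH, np.log(2.0))
        vals[:12] = np.log(0.5)
        out = abs_log_jacobian(Volume(vals, SP, default_affine(SP, SH), "metric"))
        np.testing.assert_allclose(out.values, 0.6931, atol=1e-4)

    def test_missing_propagates_and_elementwise(self, rng):
        vals = rng.standard_normal(SH)
        vals[0, 0, 0] = np.nan
        out = abs_log_jacobian(Volume(vals, SP, default_affine(SP, SH), "metric"))
        assert np.isnan(out.values[0, 0, 0])
        np.testing.assert_array_equal(out.values[1:], np.abs(vals[1:]))


class TestToCommonSpace:
    def test_identity_bridge_is_exact(self, rng):
        m = Volume(rng.random(SH), SP, default_affine(SP, SH), "metric")
        bridge = _field(np.zeros((3,) + SH))
        np.testing.assert_array_equal(to_common_space(m, bridge).values, m.values)

    def test_constant_map_stays_constant(self):
        m = Volume(np.full(SH, 2.5), SP, default_affine(SP, SH), "metric")
        bridge = exp_velocity(smooth_velocity(SH, SP, sigma_vox=3, max_vox=1.5, seed=4))
        out, valid = to_common_space(m, bridge, return_validity=True)
        np.testing.assert_allclose(out.values[valid], 2.5, atol=1e-9)


def _toy_atlas(label_values, spacing=(1.0, 1.0, 1.0)):
    labels = Volume(label_values, spacing, default_affine(spacing, label_values.shape),
                    "label")
    ids, counts = np.unique(label_values[label_values > 0], return_counts=True)
    regions = pd.DataFrame({"region_id": ids.astype(int),
                            "name": [f"r{i}" for i in ids],
                            "voxel_count": counts.astype(int),
                            "volume_mm3": counts * float(np.prod(spacing))})
    return LabelAtlas(labels, regions)


class TestRegionSummary:
    def test_constant_map_gives_constant_region_means(self):
        lab = np.zeros((12, 12, 12), dtype=np.int64)
        lab[:6] = 1
        lab[6:] = 2
        atlas = _toy_atlas(lab)
        c = Volume(np.full((12, 12, 12), 3.25), SP, atlas.labels.affine, "metric")
        table = region_summary(c, c, atlas, min_volume_mm3=10)
        assert (table["mean_displacement_mm"] == 3.25).all()

    def test_small_region_excluded_at_500mm3(self):
        """A 480 mm^3 region is dropped while a 520 mm^3 region is kept."""
        lab = np.zeros((12, 12, 12), dtype=np.int64)
        lab.flat[:480] = 1
        lab.flat[480:1000] = 2
        atlas = _toy_atlas(lab)  # 1 mm spacing: volumes 480 and 520 mm^3
        m = Volume(np.ones((12, 12, 12)), SP, atlas.labels.affine, "metric")
        table = region_summary(m, m, atlas, min_volume_mm3=500.0)
        assert list(table["region_id"]) == [2]

    def test_matches_bruteforce_per_label_means(self, rng):
        lab = rng.integers(0, 5, (14, 14, 14))
        atlas = _toy_atlas(lab)
        disp = Volume(rng.random((14, 14, 14)), SP, atlas.labels.affine, "metric")
        alj = Volume(rng.random((14, 14, 14)), SP, atlas.labels.affine, "metric")
        table = region_summary(disp, alj, atlas, min_volume_mm3=0)
        for _, row in table.iterrows():
            sel = lab == row["region_id"]
            assert abs(row["mean_displacement_mm"] - disp.values[sel].mean()) < 1e-12
            assert abs(row["mean_abs_log_jacobian"] - alj.values[sel].mean()) < 1e-12

    def test_missing_voxels_excluded_and_counted(self):
        lab = np.ones((8, 8, 8), dtype=np.int64)
        atlas = _toy_atlas(lab)
        vals = np.ones((8, 8, 8))
        vals[0] = np.nan
        m = Volume(vals, SP, atlas.labels.affine, "metric")
        table = region_summary(m, m, atlas, min_volume_mm3=0)
        assert table.iloc[0]["n_voxels_used"] == 8 * 8 * 8 - 64
        assert table.iloc[0]["mean_displacement_mm"] == 1.0

    def test_single_region_atlas_equals_whole_mask_mean(self, rng):
        lab = np.ones((10, 10, 10), dtype=np.int64)
        atlas = _toy_atlas(lab)
        m = Volume(rng.random((10, 10, 10)), SP, atlas.labels.affine, "metric")
        table = region_summary(m, m, atlas, min_volume_mm3=0)
        assert abs(table.iloc[0]["mean_displacement_mm"] - m.values.mean()) < 1e-12

    def test_no_survivors_raises(self):
        lab = np.zeros((8, 8, 8), dtype=np.int64)
        lab[0, 0, :4] = 1
        atlas = _toy_atlas(lab)
        m = Volume(np.ones((8, 8, 8)), SP, atlas.labels.affine, "metric")
        with pytest.raises(ValidationError):
            region_summary(m, m, atlas, min_volume_mm3=500.0)
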