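"""Structure tensor, helical/intrusion angles, unwrapping, profiles, histograms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoarch.io import ImageVolume, MyocardialMask
from myoarch.orientation import (
    angle_histograms,
    circumferential_fraction,
    helical_angle,
    intrusion_angle,
    ks_two_sample,
    orientation_from_vectors,
    structure_tensor,
    transmural_profiles,
    unwrap_helical,
    unwrap_profile,
)
from myoarch.phantom import make_vector_phantom
from tests.conftest import ANNULUS_SPEC


class TestStructureTensor:
    def test_eigen_contract(self, annulus_orientation, annulus_gt):
        st_f = annulus_orientation
        m = st_f.valid & annulus_gt.mask.data
        w = st_f.eigvals[m]
        assert (np.diff(w, axis=-1) <= 1e-6).all()  # descending
        assert (w >= -1e-9).all()  # positive semi-definite
        for a, b in ((st_f.v1, st_f.v2), (st_f.v1, st_f.v3), (st_f.v2, st_f.v3)):
            assert np.abs(np.sum(a[m] * b[m], axis=-1)).max() < 1e-5

    def test_uniform_volume_all_invalid(self):
        vol = ImageVolume(np.full((16, 16, 16), 3.0), (1.0,) * 3)
        st_f = structure_tensor(vol)
        assert not st_f.valid.any()

    def test_anisotropic_volume_rejected(self):
        vol = ImageVolume(np.random.default_rng(0).random((8, 8, 8)), (1.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="resample"):
            structure_tensor(vol)

    def test_recovers_fibers_on_rendered_phantom(self, annulus_orientation, annulus_gt):
        from scipy import ndimage

        interior = ndimage.binary_erosion(annulus_gt.mask.data, iterations=3)
        m = interior & annulus_orientation.valid & annulus_gt.frames.valid
        dots = np.abs(np.sum(annulus_orientation.v3 * annulus_gt.fiber_field, axis=-1))[m]
        median_err = np.median(np.degrees(np.arccos(np.clip(dots, 0, 1))))
        assert median_err < 5.0


class TestAngleDefinitions:
    def test_circumferential_fiber_has_zero_ha(self, annulus_gt):
        f = annulus_gt.frames
        orient = orientation_from_vectors(f.g3.copy(), f.valid)
        ha = helical_angle(orient, f)
        assert np.nanmax(np.abs(ha[annulus_gt.mask.data & f.valid])) < 1e-3

    def test_longitudinal_fiber_has_ha_90(self, annulus_gt):
        f = annulus_gt.frames
        ha = helical_angle(orientation_from_vectors(f.g2.copy(), f.valid), f)
        np.testing.assert_allclose(ha[annulus_gt.mask.data & f.valid], 90.0, atol=0.05)

    def test_diagonal_fiber_has_ha_45(self, annulus_gt):
        f = annulus_gt.frames
        v = (f.g2 + f.g3) / np.sqrt(2.0)
        ha = helical_angle(orientation_from_vectors(v, f.valid), f)
        np.testing.assert_allclose(ha[annulus_gt.mask.data & f.valid], 45.0, atol=0.05)

    def test_tangential_fiber_has_zero_ia(self, annulus_gt):
        f = annulus_gt.frames
        ia = intrusion_angle(orientation_from_vectors(f.g3.copy(), f.valid), f)
        assert np.nanmax(np.abs(ia[annulus_gt.mask.data & f.valid])) < 1e-3

    def test_transmural_fiber_has_ia_90(self, annulus_gt):
        f = annulus_gt.frames
        ia = intrusion_angle(orientation_from_vectors(f.g1.copy(), f.valid), f)
        np.testing.assert_allclose(ia[annulus_gt.mask.data & f.valid], 90.0, atol=0.05)

    def test_sign_flip_leaves_angles_unchanged(self, annulus_gt):
        """v3 is an axis: negating the whole field must not change any angle."""
        f = annulus_gt.frames
        o_pos = orientation_from_vectors(annulus_gt.fiber_field.copy(), f.valid)
        o_neg = orientation_from_vectors(-annulus_gt.fiber_field, f.valid)
        np.testing.assert_array_equal(helical_angle(o_pos, f), helical_angle(o_neg, f))
        np.testing.assert_array_equal(intrusion_angle(o_pos, f), intrusion_angle(o_neg, f))

    def test_ia_law_recovered_per_level(self):
        spec = dataclasses.replace(ANNULUS_SPEC, ia_base_deg=12, ia_apex_deg=-12)
        gt = make_vector_phantom(spec)
        f = gt.frames
        ia = intrusion_angle(orientation_from_vectors(gt.fiber_field.copy(), f.valid), f)
        nz = gt.mask.shape[2]
        for lo, hi, expect in ((0, nz // 5, 9.6), (2 * nz // 5, 3 * nz // 5, 0.0),
                               (4 * nz // 5, nz, -9.6)):
            sel = gt.mask.data.copy()
            sel[:, :, :lo] = False
            sel[:, :, hi:] = False
            assert np.nanmean(ia[sel]) == pytest.approx(expect, abs=2.0)


class TestUnwrapping:
    def test_wrap_through_plus_90(self):
        np.testing.assert_allclose(unwrap_profile([80, 88, -88, -80]), [80, 88, 92, 100])

    def test_no_jump_is_noop(self):
        np.testing.assert_allclose(unwrap_profile([10, 0, -10]), [10, 0, -10])

    def test_result_clipped_to_range(self):
        out = unwrap_profile([80, -85, -80, 85])
        assert out.max() < 150.0 and out.min() >= -90.0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-90, 90), min_size=2, max_size=30))
    def test_unwrapped_profiles_are_continuous(self, samples):
        out = unwrap_profile(np.asarray(samples))
        finite = out[np.isfinite(out)]
        assert (finite >= -90).all() and (finite < 150).all()
        # continuity holds wherever clipping did not interfere
        raw = np.asarray(samples)
        if len(finite) == len(raw) and (finite < 149.9).all():
            assert np.abs(np.diff(finite)).max() <= 90.0 + 1e-9

    def test_phantom_map_has_no_wrap_jumps(self, annulus_gt):
        """With the +90° endocardial law, adjacent-depth values never jump by
        90° or more after unwrapping."""
        gt = annulus_gt
        orient = orientation_from_vectors(gt.fiber_field.copy(), gt.frames.valid)
        ha_raw = helical_angle(orient, gt.frames)
        ha = unwrap_helical(ha_raw, gt.frames, gt.mask)
        # walk outward along +x spokes at several heights
        cx = (gt.mask.shape[0] - 1) // 2
        for z in (10, 40, 70):
            row = ha[:, 54, z][gt.mask.data[:, 54, z]]
            row = row[np.isfinite(row)]
            assert np.abs(np.diff(row)).max() < 90.0


class TestProfilesAndStatistics:
    def test_profile_slope_matches_law(self, annulus_gt, annulus_segments):
        """HA falling +90→−50 across a 200 μm wall gives β1 = −0.70 °/μm."""
        gt = annulus_gt
        orient = orientation_from_vectors(gt.fiber_field.copy(), gt.frames.valid)
        ha = unwrap_helical(helical_angle(orient, gt.frames), gt.frames, gt.mask)
        profiles = transmural_profiles(ha, gt.frames, annulus_segments)
        assert len(profiles) == 45
        for p in profiles:
            assert not p.insufficient
            assert p.beta1 == pytest.approx(-140.0 / 200.0, rel=0.08)
            assert p.r2 > 0.99

    def test_constant_profile_r2_zero_by_convention(self, annulus_gt, annulus_segments):
        ha = np.where(annulus_gt.mask.data, 25.0, np.nan).astype(np.float32)
        profiles = transmural_profiles(ha, annulus_gt.frames, annulus_segments)
        for p in profiles:
            assert p.beta1 == pytest.approx(0.0, abs=1e-9)
            assert p.r2 == 0.0

    def test_insufficient_bins_flagged(self, annulus_gt, annulus_segments):
        ha = np.full(annulus_gt.mask.shape, np.nan, dtype=np.float32)
        thin = annulus_gt.mask.data & (annulus_gt.frames.depth < 0.12)
        ha[thin] = 10.0
        profiles = transmural_profiles(ha, annulus_gt.frames, annulus_segments)
        assert all(p.insufficient for p in profiles)

    def test_circumferential_fraction_trivial_and_strict(self):
        region = np.ones((4, 4, 4), dtype=bool)
        assert circumferential_fraction(np.zeros((4, 4, 4)), region) == 100.0
        exact = np.full((4, 4, 4), 10.0)
        assert circumferential_fraction(exact, region) == 0.0  # strict inequality
        with pytest.raises(ValueError, match="empty"):
            circumferential_fraction(np.full((4, 4, 4), np.nan), region)

    def test_circumferential_fraction_uniform_law(self):
        """HA uniform on [−90, 90) leaves 20/180 = 11.1% in the strict band."""
        rng = np.random.default_rng(123)
        ha = rng.uniform(-90, 90, size=(40, 40, 40))
        frac = circumferential_fraction(ha, np.ones(ha.shape, dtype=bool))
        n = ha.size
        p = 20.0 / 180.0
        se = 100 * np.sqrt(p * (1 - p) / n)
        assert abs(frac - 100 * p) < 4 * se

    def test_histograms_normalised_and_ks(self, annulus_gt):
        gt = annulus_gt
        orient = orientation_from_vectors(gt.fiber_field.copy(), gt.frames.valid)
        ha = unwrap_helical(helical_angle(orient, gt.frames), gt.frames, gt.mask)
        nz = gt.mask.shape[2]
        lower = gt.mask.data.copy()
        lower[:, :, nz // 2:] = False
        upper = gt.mask.data & ~lower
        hists = angle_histograms(ha, {"lower": lower, "upper": upper})
        for h in hists.values():
            assert h["mass"].sum() == pytest.approx(1.0)
        d, p = ks_two_sample(hists["lower"]["samples"], hists["lower"]["samples"])
        assert d == 0.0

    def test_shifted_laws_detected_by_ks(self):
        spec_a = dataclasses.replace(ANNULUS_SPEC, lv_length_um=300)
        spec_b = dataclasses.replace(
            ANNULUS_SPEC, lv_length_um=300, ha_endo_deg=70, ha_epi_deg=-70
        )
        gt_a, gt_b = make_vector_phantom(spec_a), make_vector_phantom(spec_b)
        d, p = ks_two_sample(
            gt_a.ha_map[gt_a.mask.data & gt_a.frames.valid],
            gt_b.ha_map[gt_b.mask.data & gt_b.frames.valid],
        )
        assert p < 0.05
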