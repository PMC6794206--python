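"""LV axis fitting, local frames, segment models and wall thickness."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from myoarch.geometry import (
    AHA16,
    GRID45,
    LVAxis,
    assign_segments,
    build_frames,
    fit_axis,
    wall_thickness,
)
from myoarch.io import MyocardialMask
from myoarch.phantom import PhantomSpec, make_vector_phantom
from tests.conftest import ANNULUS_SPEC


class TestFitAxis:
    def test_annulus_length_within_one_voxel(self):
        # elongated annulus: the long axis dominates the voxel-cloud PCA
        spec = dataclasses.replace(
            ANNULUS_SPEC, inner_radius_um=150, outer_radius_um=250, lv_length_um=2000
        )
        gt = make_vector_phantom(spec)
        axis = fit_axis(gt.mask)
        assert abs(axis.lv_length_um - 2000.0) <= spec.voxel_um
        assert abs(axis.unit_axis @ np.array([0, 0, 1.0])) > 0.9999

    def test_landmarks_pass_through(self, annulus_gt):
        base, apex = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 503.0])
        axis = fit_axis(annulus_gt.mask, landmarks=(base, apex))
        np.testing.assert_array_equal(axis.base_point_um, base)
        np.testing.assert_array_equal(axis.apex_point_um, apex)
        assert axis.lv_length_um == 500.0

    def test_rotated_prolate_axis_recovered(self, prolate_gt):
        """Tilting the voxel cloud 30° about x must tilt the fitted axis with it."""
        spacing = np.asarray(prolate_gt.mask.spacing_um)
        idx = np.argwhere(prolate_gt.mask.data) * spacing
        ang = np.radians(30)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(ang), -np.sin(ang)], [0, np.sin(ang), np.cos(ang)]]
        )
        pts = idx @ rot.T
        pts -= pts.min(axis=0) - 2 * spacing
        grid = np.zeros(np.ceil(pts.max(axis=0) / spacing + 2).astype(int), dtype=bool)
        ijk = np.round(pts / spacing).astype(int)
        grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
        axis = fit_axis(MyocardialMask(grid, tuple(spacing)))
        true_axis = rot @ prolate_gt.axis.unit_axis
        assert np.degrees(np.arccos(abs(axis.unit_axis @ true_axis))) < 2.0

    def test_planar_mask_rejected(self):
        flat = np.zeros((20, 20, 5), dtype=bool)
        flat[2:18, 2:18, 2] = True
        with pytest.raises(ValueError, match="planar"):
            fit_axis(MyocardialMask(flat, (1.0, 1.0, 1.0)))


class TestFrames:
    def test_triads_orthonormal(self, prolate_gt):
        f = prolate_gt.frames
        m = prolate_gt.mask.data & f.valid
        for a, b in ((f.g1, f.g2), (f.g1, f.g3), (f.g2, f.g3)):
            assert np.abs(np.sum(a * b, axis=-1)[m]).max() < 1e-6
        for g in (f.g1, f.g2, f.g3):
            np.testing.assert_allclose(np.linalg.norm(g[m], axis=-1), 1.0, atol=1e-6)

    def test_right_handed(self, prolate_gt, annulus_gt):
        for gt in (prolate_gt, annulus_gt):
            f = gt.frames
            m = gt.mask.data & f.valid
            hand = np.sum(np.cross(f.g1, f.g2) * f.g3, axis=-1)[m]
            assert hand.min() > 0

    def test_equatorial_g3_horizontal_tangent(self, annulus_gt):
        """On an axis-aligned phantom, g3 lies in the slice plane tangent to
        the circular cross-section."""
        f = annulus_gt.frames
        m = annulus_gt.mask.data & f.valid
        # horizontal: no z-component beyond 1°
        assert np.abs(f.g3[m][:, 2]).max() < np.sin(np.radians(1.0))
        # tangent: perpendicular to the in-plane radial direction
        pos = np.argwhere(m) * 10.0 - np.array([535.0, 535.0, 0.0])
        radial = pos[:, :2] / np.linalg.norm(pos[:, :2], axis=1, keepdims=True)
        dots = np.abs(np.sum(f.g3[m][:, :2] * radial, axis=1))
        assert dots.max() < np.sin(np.radians(1.0))

    def test_depth_at_surfaces(self, annulus_gt):
        f = annulus_gt.frames
        md = annulus_gt.mask.data
        surf = md & ~ndimage.binary_erosion(md)
        endo = surf & ndimage.binary_dilation(f.cavity)
        epi = surf & ~endo
        epi[..., 0] = epi[..., -1] = False  # open ends are not epicardium
        assert np.percentile(f.depth[endo], 95) < 0.1
        assert np.percentile(f.depth[epi], 5) > 0.9

    def test_depth_monotone_along_outward_rays(self, annulus_gt):
        """Depth increases with radius through the wall of the annulus."""
        f = annulus_gt.frames
        md = annulus_gt.mask.data
        x = np.arange(md.shape[0]) * 10.0 - 535.0
        row = md[:, 54, 40]
        d = f.depth[:, 54, 40][row & (x > 0)]
        assert (np.diff(d) >= -1e-6).all()

    def test_on_axis_voxels_invalid(self):
        """The circumferential direction is undefined on the long axis, so
        apical-cap voxels that sit exactly on it are flagged invalid."""
        spec = PhantomSpec(
            inner_radius_um=150, outer_radius_um=330, lv_length_um=800,
            voxel_um=20, stripe_period_um=60, geometry="prolate", seed=0,
        )
        gt = make_vector_phantom(spec)
        centre = (gt.mask.shape[0] - 1) // 2
        assert gt.mask.shape[0] % 2 == 1  # grid has an exact on-axis column
        col_mask = gt.mask.data[centre, centre, :]
        assert col_mask.any()  # the apical cap crosses the axis
        assert not (gt.frames.valid[centre, centre, :] & col_mask).any()


class TestSegments:
    def test_grid45_has_45_nonempty_segments(self, annulus_segments):
        assert annulus_segments.n_segments == 45
        assert annulus_segments.nonempty_segments() == 45

    def test_aha16_sector_counts(self, annulus_gt):
        model = assign_segments(annulus_gt.mask, annulus_gt.axis, AHA16)
        assert model.n_segments == 16
        assert [model.sectors_at(lv) for lv in (1, 2, 3)] == [6, 6, 4]
        assert model.nonempty_segments() == 16

    def test_labels_partition_mask(self, annulus_gt, annulus_segments):
        md = annulus_gt.mask.data
        assert (annulus_segments.level_of[md] >= 1).all()
        assert (annulus_segments.sector_of[md] >= 1).all()
        assert (annulus_segments.layer_of[md] >= 1).all()
        assert (annulus_segments.level_of[~md] == 0).all()

    def test_layers_are_equal_count_quartiles(self, annulus_segments):
        for level, sector in ((1, 1), (3, 5), (5, 9)):
            sel = annulus_segments.segment_mask(level, sector)
            lay = annulus_segments.layer_of[sel]
            fracs = np.array([(lay == k).mean() for k in (1, 2, 3, 4)])
            assert np.abs(fracs - 0.25).max() < 0.02

    def test_truncation_unassigns_extremes(self, annulus_gt):
        model = assign_segments(
            annulus_gt.mask, annulus_gt.axis, AHA16, truncate_frac=0.05
        )
        md = annulus_gt.mask.data
        assert (model.level_of[md] == 0).any()
        assert not model.level_of[md[..., 0], ...].all()  # basal extreme dropped
        assert (model.level_of[:, :, 40][md[:, :, 40]] >= 1).all()  # mid intact


class TestWallThickness:
    def test_annulus_thickness_uniform(self, annulus_gt):
        wt = wall_thickness(annulus_gt.mask, annulus_gt.axis, frames=annulus_gt.frames)
        assert len(wt.table) == 45
        np.testing.assert_allclose(wt.table.thickness_um, 200.0, atol=10.0)

    def test_normalized_is_thickness_over_length(self, annulus_gt):
        wt = wall_thickness(annulus_gt.mask, annulus_gt.axis)
        np.testing.assert_allclose(
            wt.table.normalized, wt.table.thickness_um / annulus_gt.axis.lv_length_um
        )

    def test_prolate_spokes_match_ellipse_oracle(self, prolate_gt):
        """Ray thickness at each level mid-plane equals the analytic gap
        between the epicardial and endocardial ellipses."""
        spec = prolate_gt.spec
        wt = wall_thickness(prolate_gt.mask, prolate_gt.axis, frames=prolate_gt.frames)
        L, r_in, r_out = spec.lv_length_um, spec.inner_radius_um, spec.outer_radius_um
        wall = r_out - r_in
        L_in = L - wall
        md = prolate_gt.mask.data
        ell_lo = 0.0
        # level mid-planes replicate the implementation's equal split of the span
        pos_z = np.argwhere(md)[:, 2] * spec.voxel_um
        lo, hi = pos_z.min(), pos_z.max()
        for level in range(1, 6):
            z = lo + (level - 0.5) * (hi - lo) / 5
            rho_epi = r_out * np.sqrt(max(1 - (z / L) ** 2, 0.0))
            rho_endo = r_in * np.sqrt(max(1 - (z / L_in) ** 2, 0.0)) if z < L_in else 0.0
            expected = rho_epi - rho_endo
            got = wt.table[wt.table.level == level].thickness_um.to_numpy()
            np.testing.assert_allclose(got, expected, atol=2.5 * spec.voxel_um)

    def test_missing_ray_flagged(self):
        # half-annulus: spokes pointing into the missing half find no tissue
        n = 64
        x, y, z = np.meshgrid(*(np.arange(n) - n / 2 + 0.5,) * 3, indexing="ij")
        rho = np.sqrt(x**2 + y**2)
        mask = (rho > 15) & (rho < 25) & (x > 0)
        m = MyocardialMask(mask, (1.0, 1.0, 1.0))
        axis = LVAxis(
            np.array([n / 2 - 0.5, n / 2 - 0.5, 0.0]),
            np.array([n / 2 - 0.5, n / 2 - 0.5, float(n - 1)]),
        )
        wt = wall_thickness(m, axis)
        assert wt.table.thickness_um.isna().any()
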