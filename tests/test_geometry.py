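"""LV scaffold: profiles/thickness, depth, layers, regions, local frames."""

import numpy as np
import pytest

from cardiodti.geometry import (
    assign_regions,
    build_geometry,
    build_profiles,
    estimate_long_axis,
    local_frames,
    split_layers,
)


def annulus_masks(n=48, nz=12, r_in=10, r_out=15):
    """Axis-aligned cylindrical annulus (voxel units)."""
    idx = np.arange(n) - (n - 1) / 2
    X, Y = np.meshgrid(idx, idx, indexing="ij")
    rho = np.hypot(X, Y)
    wall2d = (rho >= r_in) & (rho <= r_out)
    cav2d = rho < r_in
    wall = np.repeat(wall2d[:, :, None], nz, axis=2)
    cav = np.repeat(cav2d[:, :, None], nz, axis=2)
    return wall, cav, np.diag([0.1, 0.1, 0.1, 1.0])


class TestProfiles:
    def test_annulus_wall_thickness_is_half_millimetre(self):
        wall, cav, affine = annulus_masks()
        _, profiles = build_profiles(wall, cav, affine)
        # inner radius 10 voxels, outer 15, at 0.1 mm: thickness 0.5 mm
        assert np.all(np.abs(profiles["thickness_mm"] - 0.5) <= 0.11)
        assert abs(profiles["thickness_mm"].mean() - 0.5) < 0.05

    def test_depth_zero_on_endo_contour_one_on_epi_contour(self):
        wall, cav, affine = annulus_masks()
        depth, _ = build_profiles(wall, cav, affine)
        from cardiodti.geometry import _slice_contours

        endo, epi = _slice_contours(wall[..., 0], cav[..., 0])
        assert np.all(depth[..., 5][endo] == 0.0)
        assert np.all(depth[..., 5][epi] == 1.0)
        assert np.nanmin(depth[wall]) >= 0.0 and np.nanmax(depth[wall]) <= 1.0

    def test_depth_monotone_along_radial_profiles(self):
        wall, cav, affine = annulus_masks()
        depth, _ = build_profiles(wall, cav, affine)
        n = depth.shape[0]
        c = (n - 1) / 2
        for theta in np.linspace(0, 2 * np.pi, 13)[:-1]:
            rr = np.arange(10, 15.5, 0.5)
            ii = np.rint(c + rr * np.cos(theta)).astype(int)
            jj = np.rint(c + rr * np.sin(theta)).astype(int)
            d = depth[ii, jj, 5]
            d = d[np.isfinite(d)]
            assert np.all(np.diff(d) >= -0.02)

    def test_empty_myocardium_rejected(self):
        with pytest.raises(ValueError, match="empty myocardium"):
            build_profiles(
                np.zeros((8, 8, 8), bool), np.zeros((8, 8, 8), bool), np.eye(4)
            )

    def test_single_contour_slice_skipped_with_warning(self, caplog):
        wall, cav, affine = annulus_masks(nz=8)
        cav[..., 3] = False  # no cavity: endo contour missing on this slice
        wall_mod = wall.copy()
        with caplog.at_level("WARNING", logger="cardiodti.geometry"):
            depth, _ = build_profiles(wall_mod, cav, affine)
        assert any("skipped" in rec.message for rec in caplog.records)
        # voxels there still receive a depth from the 3D fallback
        assert np.all(np.isfinite(depth[wall_mod[..., 3], 3]))

    def test_nearest_profile_rule_agrees_with_distance_ratio_on_annulus(self):
        wall, cav, affine = annulus_masks()
        d_ratio, _ = build_profiles(wall, cav, affine, depth_method="distance_ratio")
        d_near, _ = build_profiles(wall, cav, affine, depth_method="nearest_profile")
        sel = wall & np.isfinite(d_ratio) & np.isfinite(d_near)
        assert np.median(np.abs(d_ratio[sel] - d_near[sel])) < 0.1


class TestLayers:
    @pytest.mark.parametrize(
        "depth, expected", [(0.25, 1), (0.75, 2), (0.5, 2), (0.499, 1)]
    )
    def test_mid_wall_split_with_tie_to_subepi(self, depth, expected):
        labels = split_layers(np.array([[[depth]]]))
        assert labels[0, 0, 0] == expected

    def test_layer_split_halves_thin_wall_volume(self):
        # thin wall relative to radius: the mid-depth surface splits the
        # volume nearly evenly
        wall, cav, affine = annulus_masks(n=64, r_in=20, r_out=24)
        geom = build_geometry(wall, cav, affine)
        frac = (geom.layer_labels == 1).sum() / wall.sum()
        assert abs(frac - 0.5) <= 0.10

    def test_layer_split_of_thick_lv_wall_favors_subepicardium(self, phantom48, geom48):
        # mouse LV wall is thick relative to the cavity: the outer half of
        # the wall necessarily holds more volume, but not grotesquely so
        _, _, _, truth = phantom48
        frac = (geom48.layer_labels == 1).sum() / truth.myocardium.sum()
        assert 0.30 <= frac < 0.5


class TestRegions:
    def test_ninety_wall_slices_split_into_equal_thirds(self):
        wall, cav, _ = annulus_masks(n=24, nz=96, r_in=5, r_out=9)
        wall[..., :3] = False
        wall[..., 93:] = False  # 90 wall-bearing slices
        cav[..., :3] = False
        cav[..., 93:] = False
        regions, segments = assign_regions(wall, cav)
        per_region = [
            len(np.unique(np.argwhere(regions == code)[:, 2])) for code in (1, 2, 3)
        ]
        assert per_region == [30, 30, 30]
        # most basal (highest z) slice is labelled base
        assert np.all(regions[..., 92][wall[..., 92]] == 1)
        assert set(np.unique(segments[wall])) <= set(range(1, 18))

    def test_reference_angle_permutes_segments_not_regions(self):
        wall, cav, _ = annulus_masks(n=24, nz=9, r_in=5, r_out=9)
        r0, s0 = assign_regions(wall, cav, reference_angle=0.0)
        r1, s1 = assign_regions(wall, cav, reference_angle=60.0)
        np.testing.assert_array_equal(r0, r1)
        assert not np.array_equal(s0, s1)
        assert set(np.unique(s0[wall])) == set(np.unique(s1[wall]))

    def test_too_few_slices_rejected(self):
        wall, cav, _ = annulus_masks(nz=8)
        wall[..., 2:] = False
        cav[..., 2:] = False
        with pytest.raises(ValueError, match=">= 3"):
            assign_regions(wall, cav)

    def test_apical_cap_gets_segment_17(self, phantom48, geom48):
        _, _, _, truth = phantom48
        cap = truth.myocardium & (geom48.segment_ids == 17)
        assert cap.any()
        assert np.all(geom48.region_labels[cap] == 3)  # cap is apex


class TestLocalFrames:
    def test_cylinder_frames_match_analytic_axes(self):
        wall, cav, affine = annulus_masks()
        geom = build_geometry(wall, cav, affine)
        n = wall.shape[0]
        c = int((n - 1) / 2)
        i = c + 12  # voxel on the +x side, mid-wall
        assert geom.frame_valid[i, c, 5]
        cvec, lvec, rvec = geom.frames[i, c, 5]
        np.testing.assert_allclose(rvec, [1, 0, 0], atol=0.05)
        np.testing.assert_allclose(lvec, [0, 0, 1], atol=0.05)
        np.testing.assert_allclose(cvec, [0, 1, 0], atol=0.05)

    def test_frames_orthonormal_right_handed(self, geom48):
        f = geom48.frames[geom48.frame_valid]
        gram = np.einsum("nij,nkj->nik", f, f)
        np.testing.assert_allclose(
            gram, np.broadcast_to(np.eye(3), gram.shape), atol=1e-6
        )
        # c = l x r
        np.testing.assert_allclose(
            np.cross(f[:, 1], f[:, 2]), f[:, 0], atol=1e-6
        )

    def test_rotational_equivariance_about_long_axis(self):
        """Rotating the whole geometry rotates the frame field with it.

        A quarter-turn about the long axis maps the voxel lattice onto
        itself, so frame(R p) and R frame(p) can be compared without any
        resampling: they must agree to well under a degree.
        """
        wall, cav, affine = annulus_masks(n=64)
        depth, _ = build_profiles(wall, cav, affine)
        frames, valid = local_frames(depth, wall, affine, cavity=cav)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        c = 63 / 2
        angles = []
        for i, j in np.argwhere(valid[..., 5]):
            q = R[:2, :2] @ np.array([i - c, j - c]) + c
            iq, jq = int(round(q[0])), int(round(q[1]))
            assert valid[iq, jq, 5]
            fa = frames[i, j, 5] @ R.T  # rotate each axis row
            fb = frames[iq, jq, 5]
            cosang = np.abs(np.sum(fa * fb, axis=1)).clip(0, 1)
            angles.append(np.degrees(np.arccos(cosang)).max())
        angles = np.asarray(angles)
        assert len(angles) > 300
        assert angles.max() < 1.0

    def test_radial_axis_tracks_analytic_direction(self):
        """Estimated radial axes follow the outward normal of the annulus.

        Contour voxelization leaves a few degrees of azimuthal ripple; that
        ripple tilts the frame about the longitudinal axis, which perturbs
        helix angles only to second order.
        """
        wall, cav, affine = annulus_masks(n=64, r_in=14, r_out=26)
        depth, _ = build_profiles(wall, cav, affine)
        frames, valid = local_frames(depth, wall, affine, cavity=cav)
        idx = np.arange(64) - 63 / 2
        X, Y = np.meshgrid(idx, idx, indexing="ij")
        rho = np.hypot(X, Y)
        sel = valid[..., 5]
        r_est = frames[:, :, 5, 2, :][sel]
        r_true = np.stack([X / rho, Y / rho, np.zeros_like(X)], axis=-1)[sel]
        ang = np.degrees(
            np.arccos(np.abs(np.sum(r_est * r_true, axis=1)).clip(0, 1))
        )
        assert np.median(ang) < 3.0
        assert ang.max() < 15.0

    def test_flat_depth_voxels_flagged_not_raised(self):
        # a solid disc has no transmural direction at its centre
        wall = np.zeros((16, 16, 8), bool)
        wall[4:12, 4:12, :] = True
        cav = np.zeros_like(wall)
        depth = np.where(wall, 0.5, np.nan)
        frames, valid = local_frames(depth, wall, np.eye(4), cavity=cav)
        assert not valid[8, 8, 4]


def test_estimated_long_axis_of_phantom_is_grid_z(phantom48):
    _, _, _, truth = phantom48
    axis = estimate_long_axis(truth.myocardium)
    assert abs(axis @ np.array([0.0, 0.0, 1.0])) > 0.99


def test_wall_thickness_table_by_region(geom48):
    tab = geom48.wall_thickness_by_region()
    assert {"global", "base", "mid", "apex"} <= set(tab["region"])
    assert (tab["thickness_mm"] > 0).all()
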