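"""Angle maps, transmural profiles, and region x layer aggregation."""

import numpy as np
import pandas as pd
import pytest

from cardiodti import (
    aggregate_metrics,
    helix_angle,
    sheetlet_angle,
    tables_to_long,
    transmural_profile,
)
from cardiodti.microstructure import PROJECTION_NORM_MIN
from conftest import angular_error


@pytest.fixture()
def flat_frames():
    """Uniform frame field: c = x, l = z, r = y, all voxels valid."""
    shape = (8, 8, 8)
    frames = np.zeros(shape + (3, 3))
    frames[..., 0, :] = [1.0, 0.0, 0.0]   # circumferential
    frames[..., 1, :] = [0.0, 0.0, 1.0]   # longitudinal
    frames[..., 2, :] = [0.0, 1.0, 0.0]   # radial
    valid = np.ones(shape, dtype=bool)
    return frames, valid


def _field(shape, vec):
    out = np.zeros(shape + (3,))
    out[...] = np.asarray(vec, dtype=float)
    return out


class TestHelixAngle:
    @pytest.mark.parametrize(
        "e1, expected",
        [
            ([1, 0, 0], 0.0),                      # along c
            ([1 / np.sqrt(2), 0, 1 / np.sqrt(2)], 45.0),  # (c+l)/sqrt(2)
            ([-1 / np.sqrt(2), 0, 1 / np.sqrt(2)], -45.0),
            ([0, 0, 1], 90.0),                     # along l: folded boundary
        ],
    )
    def test_reference_orientations(self, flat_frames, e1, expected):
        frames, valid = flat_frames
        ha = helix_angle(_field((8, 8, 8), e1), frames, valid)
        assert np.all(angular_error(ha, expected) < 1e-9)

    def test_sign_flip_invariance(self, flat_frames):
        frames, valid = flat_frames
        rng = np.random.default_rng(4)
        e1 = rng.standard_normal((8, 8, 8, 3))
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        a = helix_angle(e1, frames, valid)
        b = helix_angle(-e1, frames, valid)
        sel = np.isfinite(a)
        np.testing.assert_array_equal(np.isfinite(a), np.isfinite(b))
        assert np.all(angular_error(a[sel], b[sel]) < 1e-9)

    def test_range_and_validity_threshold(self, flat_frames):
        frames, valid = flat_frames
        # nearly radial fiber: tangential projection below threshold → NaN
        e1 = _field((8, 8, 8), [0.1, np.sqrt(1 - 0.02), 0.1])
        ha = helix_angle(e1, frames, valid)
        assert np.all(np.isnan(ha))
        e1 = _field((8, 8, 8), [0, 0, 0])  # zero vector: invalid, no exception
        assert np.all(np.isnan(helix_angle(e1, frames, valid)))

    def test_recovered_map_matches_truth_on_phantom(self, phantom48, fit48, geom48):
        _, _, _, truth = phantom48
        ha = helix_angle(fit48.primary_eigenvector, geom48.frames, geom48.frame_valid)
        sel = (
            np.isfinite(ha) & np.isfinite(truth.ha) & truth.valid
            & (truth.depth >= 0.1) & (truth.depth <= 0.9)
        )
        err = angular_error(ha[sel], truth.ha[sel])
        assert np.median(err) < 1.0
        assert np.percentile(err, 95) < 3.0
        assert np.nanmin(ha) >= -90.0 and np.nanmax(ha) <= 90.0


class TestSheetletAngle:
    @pytest.mark.parametrize(
        "e2, expected",
        [
            ([0, 0, 1], 0.0),                       # E2 = l = m (E1 = c)
            ([0, 1, 0], 90.0),                      # E2 = r
            ([0, 1 / np.sqrt(2), 1 / np.sqrt(2)], 45.0),
        ],
    )
    def test_reference_orientations_with_circumferential_fiber(
        self, flat_frames, e2, expected
    ):
        frames, valid = flat_frames
        e1 = _field((8, 8, 8), [1, 0, 0])
        out = sheetlet_angle(e1, _field((8, 8, 8), e2), frames, valid)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_invariant_to_both_sign_flips(self, flat_frames):
        frames, valid = flat_frames
        rng = np.random.default_rng(5)
        e1 = rng.standard_normal((8, 8, 8, 3))
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        # e2 orthogonal to e1
        tmp = rng.standard_normal((8, 8, 8, 3))
        e2 = np.cross(e1, tmp)
        e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
        ref = sheetlet_angle(e1, e2, frames, valid)
        for s1, s2 in [(-1, 1), (1, -1), (-1, -1)]:
            out = sheetlet_angle(s1 * e1, s2 * e2, frames, valid)
            sel = np.isfinite(ref) & np.isfinite(out)
            np.testing.assert_allclose(out[sel], ref[sel], atol=1e-9)
        assert np.nanmin(ref) >= 0.0 and np.nanmax(ref) <= 90.0

    def test_prescribed_sheetlet_angle_recovered(self):
        from cardiodti import DiffusionTensorModel, PhantomSpec, build_geometry, build_phantom

        spec = PhantomSpec.for_grid(48, e2a_true=20.0)
        dwi, gtab, truth = build_phantom(spec)
        fit = DiffusionTensorModel(dwi, gtab, mask=truth.myocardium).fit()
        geom = build_geometry(truth.myocardium, truth.cavity, truth.affine)
        e2a = sheetlet_angle(
            fit.primary_eigenvector, fit.secondary_eigenvector,
            geom.frames, geom.frame_valid,
        )
        sel = np.isfinite(e2a) & truth.valid
        assert abs(np.median(e2a[sel]) - 20.0) < 3.0


class TestTransmuralProfile:
    def test_constant_field_gives_flat_profile(self):
        rng = np.random.default_rng(6)
        depth = rng.uniform(0, 1, (10, 10, 10))
        ha = np.full_like(depth, 17.0)
        prof = transmural_profile(ha, depth)
        lv = prof[prof.region == "LV"]
        np.testing.assert_allclose(lv["mean_ha_deg"], 17.0, atol=1e-9)
        assert list(lv["depth_pct"]) == [0.0, 25.0, 50.0, 75.0, 100.0]

    def test_linear_phantom_profile_recovers_prescribed_endpoints(
        self, phantom48, fit48, geom48
    ):
        _, _, _, truth = phantom48
        ha = helix_angle(fit48.primary_eigenvector, geom48.frames, geom48.frame_valid)
        prof = transmural_profile(ha, geom48.depth, geom48.region_labels)
        lv = prof[prof.region == "LV"].sort_values("depth_pct")
        expected = np.array([60.0, 30.0, 0.0, -30.0, -60.0])
        np.testing.assert_allclose(lv["mean_ha_deg"].to_numpy(), expected, atol=3.0)

    def test_empty_bin_reported_as_missing(self):
        depth = np.full((10, 10, 10), 0.5)
        ha = np.zeros_like(depth)
        prof = transmural_profile(ha, depth)
        lv = prof[prof.region == "LV"].set_index("depth_pct")
        assert lv.loc[0.0, "n_voxels"] == 0
        assert np.isnan(lv.loc[0.0, "mean_ha_deg"])
        assert lv.loc[50.0, "n_voxels"] == 1000


class TestAggregation:
    def test_uniform_metric_fills_every_cell(self, geom48):
        v = 3.25
        maps = {"MD": np.full(geom48.myocardium.shape, v)}
        tab = aggregate_metrics(maps, {}, geom48)
        assert len(tab) == 12  # 4 regions x 3 layers
        np.testing.assert_allclose(tab["MD_mean"], v, atol=1e-12)

    def test_cell_counts_partition_the_wall(self, geom48):
        maps = {"MD": np.ones(geom48.myocardium.shape)}
        tab = aggregate_metrics(maps, {}, geom48)
        parts = tab[(tab.region != "global") & (tab.layer != "global")]
        assert parts["n_voxels"].sum() == int(geom48.myocardium.sum())

    def test_global_row_is_voxel_weighted_combination(self, geom48):
        rng = np.random.default_rng(7)
        maps = {"MD": rng.uniform(0, 1, geom48.myocardium.shape)}
        tab = aggregate_metrics(maps, {}, geom48).set_index(["region", "layer"])
        parts = tab.loc[
            [(r, l) for r in ("base", "mid", "apex") for l in ("subendo", "subepi")]
        ]
        weighted = (parts["MD_mean"] * parts["n_voxels"]).sum() / parts["n_voxels"].sum()
        assert abs(weighted - tab.loc[("global", "global"), "MD_mean"]) < 1e-9

    def test_regional_group_effect_visible_in_target_cell(self):
        from cardiodti import DiffusionTensorModel, PhantomSpec, build_geometry, build_phantom

        spec = PhantomSpec.for_grid(40, region_scale={("base", "subepi"): 0.85})
        dwi, gtab, truth = build_phantom(spec)
        fit = DiffusionTensorModel(dwi, gtab, mask=truth.myocardium).fit()
        geom = build_geometry(truth.myocardium, truth.cavity, truth.affine)
        tab = aggregate_metrics({"MD": fit.md}, {}, geom).set_index(["region", "layer"])
        scaled = tab.loc[("base", "subepi"), "MD_mean"]
        ref = tab.loc[("mid", "subepi"), "MD_mean"]
        assert scaled / ref == pytest.approx(0.85, abs=0.02)

    def test_empty_cells_retained_with_zero_count(self, geom48):
        maps = {"X": np.full(geom48.myocardium.shape, np.nan)}
        tab = aggregate_metrics(maps, {}, geom48)
        assert (tab["X_mean"].isna()).all()
        assert len(tab) == 12


class TestRotationInvariance:
    def test_angles_invariant_under_simultaneous_rigid_rotation(self, flat_frames):
        """Rotating eigenvectors and frames together leaves HA and |E2A| fixed."""
        frames, valid = flat_frames
        rng = np.random.default_rng(8)
        e1 = rng.standard_normal((8, 8, 8, 3))
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        e2 = np.cross(e1, rng.standard_normal((8, 8, 8, 3)))
        e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
        theta = np.deg2rad(30.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        frames_r = frames @ R.T
        ha0 = helix_angle(e1, frames, valid)
        ha1 = helix_angle(e1 @ R.T, frames_r, valid)
        sel = np.isfinite(ha0)
        assert np.all(angular_error(ha0[sel], ha1[sel]) < 1e-9)
        s0 = sheetlet_angle(e1, e2, frames, valid)
        s1 = sheetlet_angle(e1 @ R.T, e2 @ R.T, frames_r, valid)
        sel = np.isfinite(s0) & np.isfinite(s1)
        np.testing.assert_allclose(s0[sel], s1[sel], atol=1e-9)


def test_tables_to_long_stacks_subjects():
    tab = pd.DataFrame(
        {
            "region": ["global"],
            "layer": ["global"],
            "n_voxels": [10],
            "MD_mean": [0.6],
            "MD_median": [0.59],
            "MD_sd": [0.01],
        }
    )
    long = tables_to_long({"s1": tab, "s2": tab})
    assert len(long) == 2
    assert set(long.columns) == {"subject", "region", "layer", "metric", "value"}
    assert (long.metric == "MD").all()
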