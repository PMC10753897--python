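import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteotomo.phantom import PhantomSpec, build_phantom
from osteotomo.quant import (
    connectivity_stats,
    intensity_profile,
    peak_spacing,
    plate_dimensions,
    roi_intensity_stats,
    volume_thickness_map,
)
from osteotomo.segment import connected_components_6
from osteotomo.volume import BinaryMask, Volume3D


def mask(data, voxel=1.0):
    return BinaryMask(np.asarray(data, dtype=bool), voxel)


def ball_mask(n, radius, voxel=1.0):
    c = (n - 1) / 2.0
    g = np.arange(n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return mask((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius**2, voxel)


def brute_force_thickness(m: BinaryMask, voxel: float) -> np.ndarray:
    """Literal maximal-inscribed-sphere oracle.

    Pads by one background voxel, computes each candidate centre's radius as
    the exact minimum distance to any background voxel centre, then for every
    mask voxel takes the largest sphere containing it. O(n_mask * n_bg +
    n_mask^2); only usable on small masks.
    """
    data = np.pad(m.data, 1)
    fg = np.argwhere(data).astype(np.int64)
    bg = np.argwhere(~data).astype(np.int64)
    # squared radius at each candidate centre (exact integer arithmetic)
    radii2 = np.empty(len(fg), dtype=np.int64)
    for i in range(0, len(fg), 256):
        chunk = fg[i : i + 256]
        d2 = ((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)
        radii2[i : i + 256] = d2.min(axis=1)
    # T(v) = 2 * max{ r(c) : |v - c| < r(c) }
    out = np.zeros(data.shape, dtype=np.float64)
    t = np.zeros(len(fg))
    for c, r2 in zip(fg, radii2):
        d2 = ((fg - c) ** 2).sum(axis=1)
        covered = d2 < r2
        t[covered] = np.maximum(t[covered], 2.0 * np.sqrt(r2))
    for v, val in zip(fg, t):
        out[tuple(int(x) for x in v)] = val
    return out[1:-1, 1:-1, 1:-1] * voxel


class TestThicknessMap:
    def test_solid_ball(self):
        # odd grid puts the ball center on a voxel; its maximal sphere
        # (radius sqrt(r^2 + 1)) covers the whole discrete ball
        m = ball_mask(49, 20.0)
        tm = volume_thickness_map(m, 1.0)
        vals = tm.values()
        assert np.all(np.abs(vals - 40.0) <= 1.0)  # within 1 voxel

    def test_full_length_cylinder(self):
        n, d = 41, 24.0
        g = np.arange(n) - (n - 1) / 2.0
        xx, zz = np.meshgrid(g, g, indexing="ij")
        sect = xx**2 + zz**2 <= (d / 2.0) ** 2
        m = mask(np.repeat(sect[:, None, :], 64, axis=1))
        tm = volume_thickness_map(m, 1.0)
        # volume borders count as background, so the cylinder ends pull the
        # mean down slightly; still within the 5% band of an infinite cylinder
        assert abs(tm.mean - d) / d < 0.05
        central = tm.data.data[:, 16:48, :]
        cv = central[central > 0]
        assert abs(cv.mean() - d) / d < 0.01

    def test_slab(self):
        data = np.zeros((30, 30, 30), dtype=bool)
        data[:, :, 10:17] = True  # thickness 7
        tm = volume_thickness_map(mask(data), 1.0)
        assert abs(tm.mean - 7.0) <= 1.0

    def test_values_only_on_mask(self):
        m = ball_mask(20, 6.0)
        tm = volume_thickness_map(m, 1.0)
        assert np.all(tm.data.data[~m.data] == 0)
        assert np.all(tm.data.data[m.data] > 0)

    def test_voxel_size_scales(self):
        m = ball_mask(24, 8.0, voxel=2.0)
        tm = volume_thickness_map(m, 2.0)
        assert abs(tm.mean - 32.0) < 4.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            volume_thickness_map(mask(np.zeros((4, 4, 4))), 1.0)

    def test_matches_brute_force_ball(self):
        m = ball_mask(20, 7.0)
        tm = volume_thickness_map(m, 1.0)
        oracle = brute_force_thickness(m, 1.0)
        assert np.allclose(tm.data.data, oracle)

    def test_matches_brute_force_random_blobs(self):
        from scipy import ndimage

        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            field = ndimage.gaussian_filter(rng.uniform(size=(16, 16, 16)), 2.0)
            m = mask(field > np.median(field))
            if not m.data.any():
                continue
            tm = volume_thickness_map(m, 1.0)
            oracle = brute_force_thickness(m, 1.0)
            assert np.allclose(tm.data.data, oracle), f"seed {seed}"

    def test_matches_brute_force_32cube(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[4:28, 10:20, 8:26] = True
        data[10:16, 2:30, 12:18] = True
        m = mask(data)
        tm = volume_thickness_map(m, 1.0)
        oracle = brute_force_thickness(m, 1.0)
        assert np.allclose(tm.data.data, oracle)

    def test_percentiles_ordered(self):
        m = ball_mask(24, 9.0)
        tm = volume_thickness_map(m, 1.0)
        p = tm.percentiles
        assert p[5] <= p[25] <= p[50] <= p[75] <= p[95]
        assert tm.data.data.max() <= 2.0 * 10.0  # <= inscribed-sphere bound


class TestConnectivity:
    def test_full_length_rod_extent(self):
        data = np.zeros((8, 50, 8), dtype=bool)
        data[2:6, :, 2:6] = True
        labels = connected_components_6(mask(data))
        stats = connectivity_stats(labels)
        assert stats.component_count == 1
        assert stats.max_y_extent == 50.0

    def test_two_equal_components(self):
        data = np.zeros((12, 6, 6), dtype=bool)
        data[0:3] = True
        data[8:11] = True
        stats = connectivity_stats(connected_components_6(mask(data)))
        assert stats.volume_fractions == pytest.approx([0.5, 0.5])
        assert sum(stats.volume_fractions) == pytest.approx(1.0)

    def test_finite_segment_preset_extent(self):
        from osteotomo.phantom import preset_finite_segments

        spec = preset_finite_segments()
        spec.volume_shape = (64, 640, 64)
        spec.rod_radius_top = 24.0
        spec.rod_radius_bottom = 28.0
        spec.plate_density_per_fibril = 0
        _, _, truth = build_phantom(spec)
        labels = connected_components_6(
            BinaryMask(truth.fibril_mask(), spec.voxel_size)
        )
        stats = connectivity_stats(labels)
        assert stats.max_y_extent <= 500.0 + 2 * spec.voxel_size


class TestIntensityProfile:
    def test_constant_volume(self):
        v = Volume3D(np.full((10, 10, 10), 2.5, dtype=np.float32), 1.0)
        _, vals = intensity_profile(v, (1, 1, 1), (8, 8, 8), 20)
        assert np.allclose(vals, 2.5)

    def test_reversed_endpoints(self):
        rng = np.random.default_rng(0)
        v = Volume3D(rng.uniform(size=(12, 12, 12)).astype(np.float32), 1.0)
        _, fwd = intensity_profile(v, (1, 2, 3), (9, 8, 7), 15)
        _, rev = intensity_profile(v, (9, 8, 7), (1, 2, 3), 15)
        assert np.allclose(fwd, rev[::-1])

    def test_banded_fibril_periodic(self):
        spec = PhantomSpec(
            volume_shape=(32, 268, 32),
            rod_radius_top=12.0,
            rod_radius_bottom=14.0,
            fibril_diameter_mean=20.0,
            fibril_diameter_sd=1e-6,
            fibril_fill_fraction=0.4,
            plate_density_per_fibril=0,
            seed=2,
        )
        density, _, truth = build_phantom(spec)
        cx, cz, _ = truth.fibril_axes[0]
        sx = cx + (spec.volume_shape[0] - 1) / 2.0
        sz = cz + (spec.volume_shape[2] - 1) / 2.0
        pos, vals = intensity_profile(density, (sx, 0, sz), (sx, 267, sz), 268)
        res = peak_spacing(vals, pos)
        assert res.mean_spacing == pytest.approx(67.0, abs=2.0)


class TestPeakSpacing:
    def test_pure_cosine(self):
        x = np.arange(0, 500.0)
        res = peak_spacing(np.cos(2 * np.pi * x / 67.0), x)
        assert res.mean_spacing == pytest.approx(67.0, abs=1.0)

    def test_trend_robust(self):
        x = np.arange(0, 500.0)
        res = peak_spacing(np.cos(2 * np.pi * x / 67.0) + 0.001 * x, x)
        assert res.mean_spacing == pytest.approx(67.0, abs=1.0)

    def test_constant_profile_errors(self):
        with pytest.raises(ValueError, match="maxima"):
            peak_spacing(np.ones(100))

    def test_mean_is_average_of_both(self):
        x = np.arange(0, 500.0)
        res = peak_spacing(np.cos(2 * np.pi * x / 67.0), x)
        assert res.mean_spacing == pytest.approx(
            (res.mean_max_spacing + res.mean_min_spacing) / 2.0
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(period=st.floats(min_value=30.0, max_value=120.0))
    def test_recovers_arbitrary_period(self, period):
        x = np.arange(0, 8.0 * period, 1.0)
        res = peak_spacing(np.cos(2 * np.pi * x / period), x)
        assert res.mean_spacing == pytest.approx(period, abs=1.0)


def box_mask(shape, lx, ly, lz, offset=(4, 4, 4)):
    data = np.zeros(shape, dtype=bool)
    ox, oy, oz = offset
    data[ox : ox + lx, oy : oy + ly, oz : oz + lz] = True
    return mask(data)


class TestPlateDimensions:
    def test_axis_aligned_box_exact_length_in_plane(self):
        # 100 x 7 x 35 nm box: per-xy-slice rectangle is length x thickness
        # (100 x 7), the out-of-plane z extent (35 slices) is the width
        m = box_mask((110, 17, 45), 100, 7, 35)
        dims = plate_dimensions(m, orientation_mode="length-in-plane")
        assert dims.thickness == pytest.approx(7.0)
        assert dims.length == pytest.approx(100.0)
        assert dims.width == pytest.approx(35.0)

    def test_axis_aligned_box_exact_width_in_plane(self):
        # per-xy-slice rectangle is width x thickness (35 x 7), z extent the length
        m = box_mask((45, 17, 110), 35, 7, 100)
        dims = plate_dimensions(m, orientation_mode="width-in-plane")
        assert dims.width == pytest.approx(35.0)
        assert dims.thickness == pytest.approx(7.0)
        assert dims.length == pytest.approx(100.0)

    def test_rectangle_identity_per_slice(self):
        m = box_mask((110, 17, 12), 100, 7, 4)
        dims = plate_dimensions(m, orientation_mode="length-in-plane")
        row = dims.per_slice.iloc[0]
        assert row["perimeter_2p"] == pytest.approx(214.0)
        assert row["thickness"] == pytest.approx(7.0)
        assert row["in_plane"] == pytest.approx(100.0)

    @pytest.mark.parametrize("tilt_deg,rot_axis", [(5.0, "z"), (10.0, "z"), (7.0, "x"), (10.0, "x")])
    def test_tilted_plate_within_15pct(self, tilt_deg, rot_axis):
        from osteotomo.phantom import oriented_box_mask

        # plate 100 (length, x) x 7 (thickness, y) x 35 (width, z), tilted
        # by up to 10 degrees; dimensions must still come out within 15%
        a = np.deg2rad(tilt_deg)
        c, s = np.cos(a), np.sin(a)
        if rot_axis == "z":  # in-plane rotation of the slice rectangle
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        else:  # tilts thickness/width out of the slice plane
            rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        axes = rot @ np.eye(3)
        data = oriented_box_mask((120, 40, 60), 1.0, (0.0, 0.0, 0.0), axes, (50.0, 3.5, 17.5))
        dims = plate_dimensions(mask(data), orientation_mode="length-in-plane")
        assert abs(dims.thickness - 7.0) / 7.0 <= 0.15
        assert abs(dims.length - 100.0) / 100.0 <= 0.15
        assert abs(dims.width - 35.0) / 35.0 <= 0.15

    def test_multi_component_rejected(self):
        data = np.zeros((20, 6, 6), dtype=bool)
        data[0:3, 1:3, 1:3] = True
        data[10:13, 1:3, 1:3] = True
        with pytest.raises(ValueError):
            plate_dimensions(mask(data))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plate_dimensions(mask(np.zeros((4, 4, 4))))


class TestRoiStats:
    def test_ratio_direction(self):
        data = np.zeros((8, 8, 8), dtype=np.float32)
        data[0:4] = 2.0
        data[4:8] = 1.0
        v = Volume3D(data, 1.0)
        roi = np.zeros_like(data, dtype=bool)
        roi[0:4] = True
        bg = ~roi
        m_roi, m_bg, ratio = roi_intensity_stats(v, mask(roi), mask(bg))
        assert (m_roi, m_bg) == (2.0, 1.0)
        assert ratio == 2.0

    def test_overlapping_rois_rejected(self):
        v = Volume3D(np.ones((4, 4, 4), dtype=np.float32), 1.0)
        m = mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            roi_intensity_stats(v, m, m)
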