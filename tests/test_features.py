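import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxelseg import build_pyramid
from voxelseg.features import (
    FeatureConfig,
    FeatureExtractor,
    HistogramSpec,
    LBPSpec,
    bin_indices,
    compose_features,
    histogram_at,
    lbp_code,
    lbp_plane_histogram,
    lbp_top_feature,
    plane_codes,
    slab_histograms,
)
from voxelseg.volume import Volume, iter_slabs


# --------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# --------------------------------------------------------------------------

def oracle_bin(values, k, lo, hi):
    """Bin index via edge search on the public linspace edges."""
    edges = np.linspace(lo, hi, k + 1)
    idx = np.searchsorted(edges, np.clip(values, lo, hi), side="right") - 1
    return np.clip(idx, 0, k - 1)


def oracle_cube_hist(level, coord, r, k, lo, hi):
    """Recount the (2r+1)^3 neighbourhood with clamped indices."""
    nz, ny, nx = level.shape
    z, y, x = coord
    counts = np.zeros(k, dtype=np.int64)
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                zz = min(max(z + dz, 0), nz - 1)
                yy = min(max(y + dy, 0), ny - 1)
                xx = min(max(x + dx, 0), nx - 1)
                counts[int(oracle_bin(level[zz, yy, xx], k, lo, hi))] += 1
    return counts


def oracle_lbp_code(patch):
    """Independent formulation: build the circular bit string, count
    transitions on the rotated-string comparison."""
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    centre = patch[1][1]
    bits = "".join(
        "1" if patch[1 + dy][1 + dx] >= centre else "0" for dy, dx in offsets
    )
    transitions = sum(a != b for a, b in zip(bits, bits[1:] + bits[0]))
    return bits.count("1") if transitions <= 2 else 9


def oracle_plane_code_image(plane):
    h, w = plane.shape
    padded = np.pad(plane, 1, mode="edge")
    out = np.zeros((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            out[i, j] = oracle_lbp_code(padded[i:i + 3, j:j + 3])
    return out


def oracle_code_window_hist(codes, cc, r):
    h, w = codes.shape
    counts = np.zeros(10, dtype=np.int64)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            i = min(max(cc[0] + di, 0), h - 1)
            j = min(max(cc[1] + dj, 0), w - 1)
            counts[codes[i, j]] += 1
    return counts


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

class TestSpecs:
    def test_hist_spec_validation(self):
        with pytest.raises(ValueError):
            HistogramSpec(r=0, s=0, k=8)
        with pytest.raises(ValueError):
            HistogramSpec(r=1, s=0, k=1)

    def test_lbp_code_count_fixed(self):
        with pytest.raises(ValueError):
            LBPSpec(s=0, r=1, code_count=12)

    def test_hist1_scale_pinned_to_zero(self):
        with pytest.raises(ValueError, match="scale 0"):
            FeatureConfig(
                hist1=HistogramSpec(r=2, s=1, k=8),
                hist2=HistogramSpec(r=2, s=0, k=8),
                lbp=LBPSpec(s=0, r=2),
            )

    def test_total_length_dog_rf_row(self):
        # 1 + 32 + 16 + 30 = 79
        cfg = FeatureConfig(
            hist1=HistogramSpec(r=3, s=0, k=32),
            hist2=HistogramSpec(r=12, s=0, k=16),
            lbp=LBPSpec(s=0, r=15),
        )
        assert cfg.total_length == 79

    def test_bin_edges_span_bounds(self):
        spec = HistogramSpec(r=1, s=0, k=8)
        edges = spec.bin_edges(3.0, 11.0)
        assert edges[0] == 3.0 and edges[-1] == 11.0
        assert np.all(np.diff(edges) > 0)


# --------------------------------------------------------------------------
# 3D histograms
# --------------------------------------------------------------------------

class TestHistogramAt:
    def test_constant_volume_single_bin(self):
        v = Volume(np.full((9, 9, 9), 40000, dtype=np.uint16),
                   intensity_min=0, intensity_max=65535)
        pyr = build_pyramid(v, 0)
        h = histogram_at(pyr, (4, 4, 4), HistogramSpec(r=2, s=0, k=8))
        assert h.sum() == 125
        assert np.count_nonzero(h) == 1

    def test_two_value_split_forced(self):
        # r=1 neighbourhood: 13 voxels at 0.1 and 14 at 0.9, k=2 over [0, 1]
        data = np.full((3, 3, 3), 0.9)
        flat = data.reshape(-1)
        flat[:13] = 0.1
        v = Volume(data, intensity_min=0.0, intensity_max=1.0)
        pyr = build_pyramid(v, 0)
        h = histogram_at(pyr, (1, 1, 1), HistogramSpec(r=1, s=0, k=2))
        assert list(h) == [13, 14]

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_interior_matches_brute_force(self, small_pyramid, r):
        spec = HistogramSpec(r=r, s=0, k=8)
        lo, hi = small_pyramid.intensity_min, small_pyramid.intensity_max
        for coord in [(10, 10, 10), (5, 12, 7), (r, r, r)]:
            got = histogram_at(small_pyramid, coord, spec)
            want = oracle_cube_hist(small_pyramid.level(0), coord, r, 8, lo, hi)
            assert np.array_equal(got, want)

    def test_border_matches_brute_force(self, small_pyramid):
        spec = HistogramSpec(r=2, s=0, k=16)
        lo, hi = small_pyramid.intensity_min, small_pyramid.intensity_max
        for coord in [(0, 0, 0), (19, 19, 19), (0, 10, 19)]:
            got = histogram_at(small_pyramid, coord, spec)
            want = oracle_cube_hist(small_pyramid.level(0), coord, 2, 16, lo, hi)
            assert np.array_equal(got, want)

    def test_scale_one_uses_mapped_coordinate(self, small_pyramid):
        spec = HistogramSpec(r=1, s=1, k=8)
        lo, hi = small_pyramid.intensity_min, small_pyramid.intensity_max
        got = histogram_at(small_pyramid, (7, 9, 4), spec)
        want = oracle_cube_hist(small_pyramid.level(1), (3, 4, 2), 1, 8, lo, hi)
        assert np.array_equal(got, want)


class TestSlabHistograms:
    @pytest.mark.parametrize("r,k,s", [
        (1, 8, 0), (2, 8, 0), (3, 16, 0), (4, 32, 0),
        (1, 8, 1), (2, 16, 1), (4, 32, 1),
    ])
    def test_incremental_equals_naive_everywhere(self, small_volume, r, k, s):
        pyr = build_pyramid(small_volume, 1)
        spec = HistogramSpec(r=r, s=s, k=k)
        halo = r * 2 ** s
        nz, ny, nx = small_volume.shape
        for slab in iter_slabs(small_volume, 7, halo=halo):
            H = slab_histograms(pyr, slab, spec)
            z0, z1 = slab.z_range
            coords = np.array(
                [(z, y, x) for z in range(z0, z1) for y in range(ny) for x in range(nx)]
            )
            naive = FeatureExtractor(pyr).histograms_for_coords(
                coords, spec, method="gather"
            )
            assert np.array_equal(H.reshape(-1, k), naive)

    def test_conservation_everywhere(self, small_volume):
        pyr = build_pyramid(small_volume, 0)
        spec = HistogramSpec(r=3, s=0, k=8)
        [slab] = iter_slabs(small_volume, 100, halo=3)
        H = slab_histograms(pyr, slab, spec)
        assert (H.sum(axis=-1) == 7 ** 3).all()

    def test_uniform_volume_identical_histograms(self):
        v = Volume(np.full((12, 10, 11), 123, dtype=np.uint16))
        pyr = build_pyramid(v, 0)
        [slab] = iter_slabs(v, 100, halo=2)
        H = slab_histograms(pyr, slab, HistogramSpec(r=2, s=0, k=8))
        assert (H == H[0, 0, 0]).all()

    def test_insufficient_halo_rejected(self, small_volume):
        pyr = build_pyramid(small_volume, 1)
        slab = next(iter_slabs(small_volume, 5, halo=1))
        with pytest.raises(ValueError, match="halo of 4"):
            slab_histograms(pyr, slab, HistogramSpec(r=2, s=1, k=8))

    def test_brute_force_oracle_subset(self, small_pyramid, small_volume):
        # independent recount oracle over a random coordinate subset
        spec = HistogramSpec(r=2, s=0, k=8)
        lo, hi = small_pyramid.intensity_min, small_pyramid.intensity_max
        [slab] = iter_slabs(small_volume, 100, halo=2)
        H = slab_histograms(small_pyramid, slab, spec)
        r = np.random.default_rng(3)
        for _ in range(25):
            z, y, x = (int(v) for v in r.integers(0, 20, 3))
            want = oracle_cube_hist(small_pyramid.level(0), (z, y, x), 2, 8, lo, hi)
            assert np.array_equal(H[z, y, x], want)


# --------------------------------------------------------------------------
# LBP
# --------------------------------------------------------------------------

class TestLbpCode:
    def test_all_equal_is_code_8(self):
        assert lbp_code(np.full((3, 3), 5.0)) == 8

    def test_centre_strictly_greater_is_code_0(self):
        patch = np.zeros((3, 3))
        patch[1, 1] = 1.0
        assert lbp_code(patch) == 0

    def test_alternating_neighbours_nonuniform(self):
        patch = np.zeros((3, 3))
        patch[1, 1] = 0.5
        # set alternating ring positions above the centre
        ring = [(0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0)]
        for i, (a, b) in enumerate(ring):
            patch[a, b] = 1.0 if i % 2 == 0 else 0.0
        assert lbp_code(patch) == 9

    def test_exactly_ten_codes_over_all_patterns(self):
        ring = [(0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0)]
        codes = set()
        for pattern in range(256):
            patch = np.full((3, 3), 0.5)
            for i, (a, b) in enumerate(ring):
                patch[a, b] = 1.0 if (pattern >> i) & 1 else 0.0
            codes.add(lbp_code(patch))
        assert codes == set(range(10))

    def test_rotation_invariance_exhaustive(self):
        ring = [(0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0)]

        def code_of(pattern):
            patch = np.full((3, 3), 0.5)
            for i, (a, b) in enumerate(ring):
                patch[a, b] = 1.0 if (pattern >> i) & 1 else 0.0
            return lbp_code(patch)

        for pattern in range(256):
            base = code_of(pattern)
            for rot in range(8):
                rotated = ((pattern << rot) | (pattern >> (8 - rot))) & 0xFF
                assert code_of(rotated) == base

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            patch = rng.random((3, 3))
            assert lbp_code(patch) == oracle_lbp_code(patch.tolist())

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_code_in_range_property(self, values):
        patch = np.array(values).reshape(3, 3)
        assert 0 <= lbp_code(patch) <= 9

    def test_plane_codes_matches_per_pixel(self, rng):
        plane = rng.random((12, 14))
        assert np.array_equal(plane_codes(plane), oracle_plane_code_image(plane))


class TestLbpPlaneHistogram:
    def test_constant_plane_all_code_8(self):
        level = np.full((8, 8, 8), 3.0)
        h = lbp_plane_histogram(level, (4, 4, 4), "xy", 2)
        assert h[8] == 25 and h.sum() == 25

    def test_r1_sums_to_nine(self, small_pyramid):
        h = lbp_plane_histogram(small_pyramid.level(0), (5, 5, 5), "yz", 1)
        assert h.sum() == 9

    @pytest.mark.parametrize("plane", ["xy", "yz", "xz"])
    def test_matches_brute_force(self, small_pyramid, plane):
        level = small_pyramid.level(0)
        for coord in [(10, 9, 8), (0, 0, 0), (19, 10, 19)]:
            got = lbp_plane_histogram(level, coord, plane, 3)
            z, y, x = coord
            if plane == "xy":
                codes, cc = oracle_plane_code_image(level[z]), (y, x)
            elif plane == "yz":
                codes, cc = oracle_plane_code_image(level[:, :, x]), (z, y)
            else:
                codes, cc = oracle_plane_code_image(level[:, y, :]), (z, x)
            assert np.array_equal(got, oracle_code_window_hist(codes, cc, 3))


class TestLbpTopFeature:
    def test_length_is_30(self, small_pyramid):
        f = lbp_top_feature(small_pyramid, (10, 10, 10), LBPSpec(s=0, r=4))
        assert f.shape == (30,)

    def test_constant_volume_counts_at_code8_slots(self):
        v = Volume(np.full((16, 16, 16), 9999, dtype=np.uint16))
        pyr = build_pyramid(v, 0)
        f = lbp_top_feature(pyr, (8, 8, 8), LBPSpec(s=0, r=2))
        expected = np.zeros(30, dtype=np.int64)
        expected[[8, 18, 28]] = 25
        assert np.array_equal(f, expected)

    def test_z_gradient_volume_block_structure(self):
        # varies only along z: the xy block sees a constant plane, while
        # yz / xz blocks see the gradient
        data = np.broadcast_to(
            np.linspace(0.1, 0.9, 16)[:, None, None], (16, 16, 16)
        ).copy()
        pyr = build_pyramid(Volume(data), 0)
        f = lbp_top_feature(pyr, (8, 8, 8), LBPSpec(s=0, r=2))
        constant_plane = np.zeros(10, dtype=np.int64)
        constant_plane[8] = 25
        assert np.array_equal(f[:10], constant_plane)
        assert not np.array_equal(f[10:20], constant_plane)
        assert not np.array_equal(f[20:30], constant_plane)
        # yz and xz planes are statistically identical for a pure z ramp
        assert np.array_equal(f[10:20], f[20:30])

    def test_consistent_with_plane_histograms(self, small_pyramid):
        spec = LBPSpec(s=1, r=2)
        coord = (11, 13, 6)
        f = lbp_top_feature(small_pyramid, coord, spec)
        level = small_pyramid.level(1)
        mapped = tuple(c // 2 for c in coord)
        parts = [
            lbp_plane_histogram(level, mapped, p, 2) for p in ("xy", "yz", "xz")
        ]
        assert np.array_equal(f, np.concatenate(parts))


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

def _config():
    return FeatureConfig(
        hist1=HistogramSpec(r=2, s=0, k=8),
        hist2=HistogramSpec(r=2, s=1, k=8),
        lbp=LBPSpec(s=0, r=2),
    )


class TestComposeFeatures:
    def test_row_order_and_determinism(self, small_pyramid):
        coords = np.array([[3, 4, 5], [3, 4, 5], [10, 10, 10]])
        fm = compose_features(small_pyramid, coords, _config())
        assert fm.rows.shape == (3, _config().total_length)
        assert np.array_equal(fm.rows[0], fm.rows[1])
        fm2 = compose_features(small_pyramid, coords, _config())
        assert np.array_equal(fm.rows, fm2.rows)

    def test_intensity_column_is_stored_value(self, small_pyramid, small_volume):
        coords = np.array([[2, 3, 4], [19, 0, 7]])
        fm = compose_features(small_pyramid, coords, _config())
        assert fm.rows[0, 0] == small_volume.data[2, 3, 4]
        assert fm.rows[1, 0] == small_volume.data[19, 0, 7]

    def test_normalised_blocks_sum_to_one(self, small_pyramid):
        cfg = _config()
        fm = compose_features(small_pyramid, np.array([[5, 5, 5]]), cfg)
        row = fm.rows[0]
        h1 = row[1:1 + cfg.hist1.k]
        h2 = row[1 + cfg.hist1.k:1 + cfg.hist1.k + cfg.hist2.k]
        lbp = row[-30:]
        assert np.isclose(h1.sum(), 1.0)
        assert np.isclose(h2.sum(), 1.0)
        assert np.isclose(lbp.sum(), 3.0)  # three planes, each summing to 1

    def test_counts_mode_conserves(self, small_pyramid):
        cfg = _config()
        fm = compose_features(small_pyramid, np.array([[0, 0, 0]]), cfg,
                              normalise=False)
        row = fm.rows[0]
        assert row[1:9].sum() == 125
        assert row[9:17].sum() == 125
        assert row[-30:].sum() == 3 * 25

    def test_blockwise_equals_coordwise(self, textured_20):
        volume, _, _ = textured_20
        pyr = build_pyramid(volume, 1)
        cfg = _config()
        ext = FeatureExtractor(pyr)
        nz, ny, nx = volume.shape
        whole = ext.block_features(0, nz, cfg)
        # slab-wise concatenation equals the whole-volume computation
        parts = [ext.block_features(z0, min(z0 + 6, nz), cfg)
                 for z0 in range(0, nz, 6)]
        assert np.array_equal(np.vstack(parts), whole)
        coords = np.array(
            [(z, y, x) for z in range(nz) for y in range(ny) for x in range(nx)]
        )
        sparse = ext.features_for_coords(coords, cfg, method="gather")
        assert np.allclose(whole, sparse)

    def test_translation_consistency(self, rng):
        data = rng.integers(0, 65536, size=(24, 24, 24), dtype=np.uint16)
        shifted = np.roll(data, shift=(1, 2, 3), axis=(0, 1, 2))
        cfg = FeatureConfig(
            hist1=HistogramSpec(r=2, s=0, k=8),
            hist2=HistogramSpec(r=3, s=0, k=8),
            lbp=LBPSpec(s=0, r=2),
        )
        bounds = (0.0, 65535.0)
        pyr_a = build_pyramid(Volume(data, intensity_min=0, intensity_max=65535), 0)
        pyr_b = build_pyramid(Volume(shifted, intensity_min=0, intensity_max=65535), 0)
        a = compose_features(pyr_a, np.array([[10, 10, 10]]), cfg, bounds=bounds)
        b = compose_features(pyr_b, np.array([[11, 12, 13]]), cfg, bounds=bounds)
        assert np.array_equal(a.rows, b.rows)

    def test_dense_route_equals_gather_route(self, textured_32):
        volume, _, _ = textured_32
        pyr = build_pyramid(volume, 2)
        ext = FeatureExtractor(pyr)
        r = np.random.default_rng(8)
        coords = np.column_stack([r.integers(0, 32, 300) for _ in range(3)])
        for spec in (HistogramSpec(r=32, s=0, k=16), HistogramSpec(r=7, s=2, k=8)):
            dense = ext.histograms_for_coords(coords, spec, method="dense")
            gather = ext.histograms_for_coords(coords, spec, method="gather")
            assert np.array_equal(dense, gather)
        for spec in (LBPSpec(s=0, r=32), LBPSpec(s=1, r=5)):
            dense = ext.lbp_for_coords(coords, spec, method="dense")
            gather = ext.lbp_for_coords(coords, spec, method="gather")
            assert np.array_equal(dense, gather)

    def test_bin_indices_clamps_out_of_range(self):
        idx = bin_indices(np.array([-5.0, 0.5, 99.0]), 4, 0.0, 1.0)
        assert list(idx) == [0, 2, 3]

    def test_degenerate_range_single_bin(self):
        idx = bin_indices(np.array([7.0, 7.0]), 8, 7.0, 7.0)
        assert list(idx) == [0, 0]
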