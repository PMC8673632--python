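"""Per-voxel feature vectors: intensity, neighbourhood histograms, LBP-TOP.

The feature vector for a voxel is the concatenation of

* the voxel's own intensity at scale 0,
* a short-range k-bin intensity histogram over the cube of side ``2r+1``
  at scale 0,
* a long-range k-bin intensity histogram at a configurable scale,
* three-orthogonal-plane local binary pattern code histograms
  (10 uniform rotation-invariant codes per plane, 30 features total).

Histogram bins are linearly spaced over the *scale-0* volume's recorded
global intensity range; values outside (possible only after blurring)
are clamped into the end bins.  All neighbourhoods use edge-replication
at borders — implemented uniformly as index-clamped gathers — so every
histogram sums to its full neighbourhood size.

Two computation paths exist and are tested against each other: a direct
per-voxel path (``histogram_at``/``compose_features``) and a dense slab
path (``slab_histograms``/``FeatureExtractor.block_features``) in which
the neighbourhood histogram of each successive voxel along z is obtained
incrementally from its predecessor by subtracting the outgoing ``z - r``
plane and adding the incoming ``z + r + 1`` plane, an O(r^2) update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from voxelseg.pyramid import Pyramid, map_coordinate
from voxelseg.volume import SlabView

# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

LBP_CODE_COUNT = 10
LBP_PLANES = ("xy", "yz", "xz")
LBP_FEATURE_LENGTH = LBP_CODE_COUNT * len(LBP_PLANES)

#: Tie rule: a neighbour equal to the centre contributes a set bit.
LBP_TIE_IS_ONE = True


@dataclass(frozen=True)
class HistogramSpec:
    """Neighbourhood intensity histogram: radius ``r``, scale ``s``, ``k`` bins."""

    r: int
    s: int
    k: int

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("histogram radius must be >= 1")
        if self.k < 2:
            raise ValueError("histogram bin count must be >= 2")
        if self.s < 0:
            raise ValueError("scale must be >= 0")

    @property
    def neighbourhood_size(self) -> int:
        return (2 * self.r + 1) ** 3

    def bin_edges(self, lo: float, hi: float) -> np.ndarray:
        return np.linspace(lo, hi, self.k + 1)


@dataclass(frozen=True)
class LBPSpec:
    """Three-orthogonal-plane LBP histogram: scale ``s``, 2D radius ``r``."""

    s: int
    r: int
    code_count: int = LBP_CODE_COUNT

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("LBP histogram radius must be >= 1")
        if self.s < 0:
            raise ValueError("scale must be >= 0")
        if self.code_count != LBP_CODE_COUNT:
            raise ValueError(f"code_count is fixed at {LBP_CODE_COUNT}")

    @property
    def neighbourhood_size(self) -> int:
        return (2 * self.r + 1) ** 2


@dataclass(frozen=True)
class FeatureConfig:
    """The four-part feature recipe.  ``hist1`` is pinned to scale 0."""

    hist1: HistogramSpec
    hist2: HistogramSpec
    lbp: LBPSpec
    include_intensity: bool = True

    def __post_init__(self) -> None:
        if self.hist1.s != 0:
            raise ValueError("hist1 (short-range histogram) must use scale 0")

    @property
    def total_length(self) -> int:
        return (
            (1 if self.include_intensity else 0)
            + self.hist1.k
            + self.hist2.k
            + LBP_FEATURE_LENGTH
        )

    @property
    def max_scale(self) -> int:
        return max(self.hist2.s, self.lbp.s)

    def required_halo(self) -> int:
        """Scale-0 halo (in slices) covering every neighbourhood, incl. the
        +-1 ring needed to compute LBP codes at the window edge."""
        return max(
            self.hist1.r,
            self.hist2.r * 2 ** self.hist2.s,
            (self.lbp.r + 1) * 2 ** self.lbp.s,
        )

    def to_dict(self) -> dict:
        return {
            "hist1": {"r": self.hist1.r, "s": self.hist1.s, "k": self.hist1.k},
            "hist2": {"r": self.hist2.r, "s": self.hist2.s, "k": self.hist2.k},
            "lbp": {"s": self.lbp.s, "r": self.lbp.r},
            "include_intensity": self.include_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            hist1=HistogramSpec(**d["hist1"]),
            hist2=HistogramSpec(**d["hist2"]),
            lbp=LBPSpec(**d["lbp"]),
            include_intensity=d.get("include_intensity", True),
        )


@dataclass
class FeatureMatrix:
    """Feature rows plus the scale-0 coordinates they came from."""

    rows: np.ndarray
    row_coords: np.ndarray
    config: FeatureConfig


# --------------------------------------------------------------------------
# LBP codes
# --------------------------------------------------------------------------

# Neighbour traversal: start at (row-1, col), proceed clockwise.
_LBP_OFFSETS = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


def _build_code_lut() -> np.ndarray:
    lut = np.empty(256, dtype=np.uint8)
    for p in range(256):
        bits = [(p >> i) & 1 for i in range(8)]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        lut[p] = sum(bits) if transitions <= 2 else 9
    return lut


_CODE_LUT = _build_code_lut()


def lbp_code(patch3x3: np.ndarray) -> int:
    """Uniform rotation-invariant LBP code (0..9) of a 3x3 patch.

    The 8 neighbours are thresholded against the centre (>= means bit 1)
    in fixed clockwise order; a circular bit string with <= 2 transitions
    maps to its set-bit count, everything else to the non-uniform code 9.
    """
    patch = np.asarray(patch3x3)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3x3 patch, got shape {patch.shape}")
    centre = patch[1, 1]
    pattern = 0
    for i, (dy, dx) in enumerate(_LBP_OFFSETS):
        if patch[1 + dy, 1 + dx] >= centre:
            pattern |= 1 << i
    return int(_CODE_LUT[pattern])


def plane_codes(plane: np.ndarray) -> np.ndarray:
    """LBP code of every pixel of a 2D plane, with edge padding for the 3x3."""
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError("plane must be 2D")
    padded = np.pad(plane, 1, mode="edge")
    h, w = plane.shape
    pattern = np.zeros((h, w), dtype=np.uint8)
    for i, (dy, dx) in enumerate(_LBP_OFFSETS):
        nb = padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
        pattern |= (nb >= plane).astype(np.uint8) << i
    return _CODE_LUT[pattern]


# --------------------------------------------------------------------------
# Low-level helpers
# --------------------------------------------------------------------------

def bin_indices(values: np.ndarray, k: int, lo: float, hi: float) -> np.ndarray:
    """Linear bin index in [0, k) for each value; out-of-range clamps to
    the end bins; a degenerate range maps everything to bin 0."""
    values = np.asarray(values)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    idx = np.floor((values.astype(np.float64) - lo) * (k / (hi - lo)))
    return np.clip(idx, 0, k - 1).astype(np.int64)


def _clamped_range(lo: int, hi: int, n: int) -> np.ndarray:
    """Indices lo..hi-1 clamped into [0, n) — edge replication by gather."""
    return np.clip(np.arange(lo, hi), 0, n - 1)


def _box1(a: np.ndarray, r: int, axis: int) -> np.ndarray:
    """Sliding-window (2r+1) sums along ``axis`` of an already padded array."""
    w = 2 * r + 1
    cs = np.cumsum(a, axis=axis, dtype=np.int32)
    zshape = list(a.shape)
    zshape[axis] = 1
    cs = np.concatenate([np.zeros(zshape, dtype=np.int32), cs], axis=axis)
    hi = [slice(None)] * a.ndim
    lo = [slice(None)] * a.ndim
    hi[axis] = slice(w, None)
    lo[axis] = slice(0, a.shape[axis] - w + 1)
    return cs[tuple(hi)] - cs[tuple(lo)]


def _window_hist_2d(idx: np.ndarray, r: int, k: int) -> np.ndarray:
    """Per-pixel (2r+1)^2 window histograms of a 2D index image that is
    already padded by ``r`` on both axes.  Returns (H, W, k) counts."""
    onehot = (idx[..., None] == np.arange(k)).astype(np.int32)
    return _box1(_box1(onehot, r, axis=0), r, axis=1)


def _rows_bincount(idx: np.ndarray, k: int) -> np.ndarray:
    """Row-wise bincount of an (n, m) index array into (n, k) counts."""
    n = idx.shape[0]
    offset = (np.arange(n, dtype=np.int64) * k)[:, None]
    flat = (idx.astype(np.int64) + offset).ravel()
    return np.bincount(flat, minlength=n * k).reshape(n, k).astype(np.int64)


# --------------------------------------------------------------------------
# Feature extractor
# --------------------------------------------------------------------------

class FeatureExtractor:
    """Computes feature vectors against one pyramid, caching binned levels
    and LBP code volumes across calls (and across configs during search).

    ``bounds`` overrides the histogram bin range; at inference time the
    bounds stored in the trained model are passed here so binning matches
    training exactly.
    """

    def __init__(self, pyramid: Pyramid, bounds: tuple[float, float] | None = None):
        self.pyramid = pyramid
        if bounds is None:
            bounds = (pyramid.intensity_min, pyramid.intensity_max)
        self.lo, self.hi = float(bounds[0]), float(bounds[1])
        self._bins: dict[tuple[int, int], np.ndarray] = {}
        self._codes: dict[tuple[int, str], np.ndarray] = {}

    # -- caches ------------------------------------------------------------

    def binned_level(self, s: int, k: int) -> np.ndarray:
        key = (s, k)
        if key not in self._bins:
            self._bins[key] = bin_indices(self.pyramid.level(s), k, self.lo, self.hi)
        return self._bins[key]

    def code_volume(self, s: int, plane: str) -> np.ndarray:
        """LBP codes of every voxel of level ``s`` in the given plane."""
        key = (s, plane)
        if key not in self._codes:
            level = self.pyramid.level(s)
            codes = np.empty(level.shape, dtype=np.uint8)
            if plane == "xy":
                for z in range(level.shape[0]):
                    codes[z] = plane_codes(level[z])
            elif plane == "yz":
                for x in range(level.shape[2]):
                    codes[:, :, x] = plane_codes(level[:, :, x])
            elif plane == "xz":
                for y in range(level.shape[1]):
                    codes[:, y, :] = plane_codes(level[:, y, :])
            else:
                raise ValueError(f"unknown plane {plane!r}")
            self._codes[key] = codes
        return self._codes[key]

    # -- shared coordinate mapping ----------------------------------------

    @staticmethod
    def _mapped(coords: np.ndarray, s: int, level_shape: tuple) -> np.ndarray:
        """Floor-map scale-0 coordinates to scale ``s``, clamped into the
        level (trailing partial blocks map to the last level voxel)."""
        cs = coords // (2 ** s)
        return np.minimum(cs, np.asarray(level_shape, dtype=np.int64) - 1)

    def _mapped_z_range(self, z0: int, z1: int, s: int) -> tuple[int, int]:
        nzs = self.pyramid.level(s).shape[0]
        f = 2 ** s
        return min(z0 // f, nzs - 1), min((z1 - 1) // f, nzs - 1) + 1

    # -- sparse (per-coordinate) path -------------------------------------

    def histograms_for_coords(
        self, coords: np.ndarray, spec: HistogramSpec, method: str = "auto"
    ) -> np.ndarray:
        """Neighbourhood histogram counts, one row per scale-0 coordinate.

        ``method='gather'`` forces the direct per-voxel recount (the naive
        route used as the oracle's counterpart); ``'dense'`` forces the
        incremental slab route sliced at the requested coordinates;
        ``'auto'`` picks whichever is cheaper (identical results either
        way — that equivalence is itself under test).
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
        b = self.binned_level(spec.s, spec.k)
        nz, ny, nx = b.shape
        cs = self._mapped(coords, spec.s, b.shape)
        r, k = spec.r, spec.k
        if method == "auto":
            zs_unique = np.unique(cs[:, 0])
            gather_cost = len(cs) * (2 * r + 1) ** 3
            dense_cost = len(zs_unique) * (2 * r + 1) * ny * nx * k
            method = "dense" if dense_cost < gather_cost else "gather"
        if method == "dense":
            out = np.empty((len(cs), k), dtype=np.int64)
            for z in np.unique(cs[:, 0]):
                H = self._dense_level_histograms(spec.s, int(z), int(z) + 1, r, k)[0]
                sel = cs[:, 0] == z
                out[sel] = H[cs[sel, 1], cs[sel, 2]]
            return out
        if method != "gather":
            raise ValueError(f"unknown method {method!r}")
        d = np.arange(-r, r + 1)
        w = 2 * r + 1
        n = len(cs)
        out = np.empty((n, k), dtype=np.int64)
        # chunk so the gathered window block stays modest in memory
        chunk = max(1, int(2e7 // (w ** 3)))
        for i0 in range(0, n, chunk):
            c = cs[i0:i0 + chunk]
            zz = np.clip(c[:, 0, None] + d, 0, nz - 1)
            yy = np.clip(c[:, 1, None] + d, 0, ny - 1)
            xx = np.clip(c[:, 2, None] + d, 0, nx - 1)
            block = b[zz[:, :, None, None], yy[:, None, :, None], xx[:, None, None, :]]
            out[i0:i0 + chunk] = _rows_bincount(block.reshape(len(c), -1), k)
        return out

    def lbp_for_coords(
        self, coords: np.ndarray, spec: LBPSpec, method: str = "auto"
    ) -> np.ndarray:
        """Three-orthogonal-plane LBP histogram counts (n, 30)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
        shape_s = self.pyramid.level(spec.s).shape
        cs = self._mapped(coords, spec.s, shape_s)
        n = len(cs)
        r = spec.r
        if method == "auto":
            zs_unique = np.unique(cs[:, 0])
            gather_cost = n * 3 * (2 * r + 1) ** 2
            dense_cost = (
                len(zs_unique) * (shape_s[1] + shape_s[2]) * shape_s[1] * shape_s[2]
            )
            method = "dense" if dense_cost < gather_cost else "gather"
        if method == "dense":
            out = np.empty((n, LBP_FEATURE_LENGTH), dtype=np.int64)
            for z in np.unique(cs[:, 0]):
                block = self._dense_level_lbp(spec.s, int(z), int(z) + 1, r)[0]
                sel = cs[:, 0] == z
                out[sel] = block[cs[sel, 1], cs[sel, 2]]
            return out
        if method != "gather":
            raise ValueError(f"unknown method {method!r}")
        d = np.arange(-r, r + 1)
        out = np.empty((n, LBP_FEATURE_LENGTH), dtype=np.int64)
        for pi, plane in enumerate(LBP_PLANES):
            codes = self.code_volume(spec.s, plane)
            nz, ny, nx = codes.shape
            if plane == "xy":
                aa = np.clip(cs[:, 1, None] + d, 0, ny - 1)
                bb = np.clip(cs[:, 2, None] + d, 0, nx - 1)
                block = codes[cs[:, 0][:, None, None], aa[:, :, None], bb[:, None, :]]
            elif plane == "yz":
                aa = np.clip(cs[:, 0, None] + d, 0, nz - 1)
                bb = np.clip(cs[:, 1, None] + d, 0, ny - 1)
                block = codes[aa[:, :, None], bb[:, None, :], cs[:, 2][:, None, None]]
            else:  # xz
                aa = np.clip(cs[:, 0, None] + d, 0, nz - 1)
                bb = np.clip(cs[:, 2, None] + d, 0, nx - 1)
                block = codes[aa[:, :, None], cs[:, 1][:, None, None], bb[:, None, :]]
            counts = _rows_bincount(block.reshape(n, -1), LBP_CODE_COUNT)
            out[:, pi * LBP_CODE_COUNT:(pi + 1) * LBP_CODE_COUNT] = counts
        return out

    def features_for_coords(
        self,
        coords: np.ndarray,
        config: FeatureConfig,
        normalise: bool = True,
        method: str = "auto",
    ) -> np.ndarray:
        """Full feature rows for scale-0 coordinates, in the canonical
        [intensity | hist1 | hist2 | lbp] layout."""
        coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
        parts = []
        if config.include_intensity:
            level0 = self.pyramid.level(0)
            parts.append(
                level0[coords[:, 0], coords[:, 1], coords[:, 2]]
                .astype(np.float64)[:, None]
            )
        for spec in (config.hist1, config.hist2):
            h = self.histograms_for_coords(coords, spec, method=method)
            h = h.astype(np.float64)
            if normalise:
                h /= spec.neighbourhood_size
            parts.append(h)
        l = self.lbp_for_coords(coords, config.lbp, method=method).astype(np.float64)
        if normalise:
            l /= config.lbp.neighbourhood_size
        parts.append(l)
        return np.concatenate(parts, axis=1)

    # -- dense (slab) path -------------------------------------------------

    def dense_histograms(
        self, z0: int, z1: int, spec: HistogramSpec
    ) -> np.ndarray:
        """Histogram counts for every scale-0 voxel with z in [z0, z1),
        shape (z1-z0, ny, nx, k), via the incremental plane update.

        The first neighbourhood per z-walk is computed in full; every
        subsequent one subtracts the outgoing z - r plane histogram and
        adds the incoming z + r + 1 plane histogram (O(r^2) per voxel).
        """
        s, r, k = spec.s, spec.r, spec.k
        zs0, zs1 = self._mapped_z_range(z0, z1, s)
        level_h = self._dense_level_histograms(s, zs0, zs1, r, k)
        return self._upsample(level_h, z0, z1, zs0, s)

    def _dense_level_histograms(
        self, s: int, zs0: int, zs1: int, r: int, k: int
    ) -> np.ndarray:
        b = self.binned_level(s, k)
        nz, ny, nx = b.shape
        zsel = _clamped_range(zs0 - r, zs1 + r, nz)
        ysel = _clamped_range(-r, ny + r, ny)
        xsel = _clamped_range(-r, nx + r, nx)
        bp = b[np.ix_(zsel, ysel, xsel)]
        # per-plane 2D window histograms
        plane_h = np.empty((bp.shape[0], ny, nx, k), dtype=np.int32)
        for i in range(bp.shape[0]):
            plane_h[i] = _window_hist_2d(bp[i], r, k)
        dz = zs1 - zs0
        out = np.empty((dz, ny, nx, k), dtype=np.int32)
        out[0] = plane_h[: 2 * r + 1].sum(axis=0, dtype=np.int32)
        for j in range(1, dz):
            # incremental: drop plane (z - r), add plane (z + r + 1)
            np.subtract(out[j - 1], plane_h[j - 1], out=out[j])
            out[j] += plane_h[j + 2 * r]
        return out

    def dense_lbp(self, z0: int, z1: int, spec: LBPSpec) -> np.ndarray:
        """LBP-TOP counts for every scale-0 voxel with z in [z0, z1),
        shape (z1-z0, ny, nx, 30)."""
        zs0, zs1 = self._mapped_z_range(z0, z1, spec.s)
        level_arr = self._dense_level_lbp(spec.s, zs0, zs1, spec.r)
        return self._upsample(level_arr, z0, z1, zs0, spec.s)

    def _dense_level_lbp(self, s: int, zs0: int, zs1: int, r: int) -> np.ndarray:
        dz = zs1 - zs0
        nz, ny, nx = self.pyramid.level(s).shape
        out = np.empty((dz, ny, nx, LBP_FEATURE_LENGTH), dtype=np.int32)
        for pi, plane in enumerate(LBP_PLANES):
            codes = self.code_volume(s, plane)
            sl = slice(pi * LBP_CODE_COUNT, (pi + 1) * LBP_CODE_COUNT)
            if plane == "xy":
                ysel = _clamped_range(-r, ny + r, ny)
                xsel = _clamped_range(-r, nx + r, nx)
                for j, z in enumerate(range(zs0, zs1)):
                    out[j, :, :, sl] = _window_hist_2d(
                        codes[z][np.ix_(ysel, xsel)], r, LBP_CODE_COUNT
                    )
            elif plane == "yz":
                zsel = _clamped_range(zs0 - r, zs1 + r, nz)
                ysel = _clamped_range(-r, ny + r, ny)
                cp = codes[np.ix_(zsel, ysel, np.arange(nx))]
                for x in range(nx):
                    out[:, :, x, sl] = _window_hist_2d(cp[:, :, x], r, LBP_CODE_COUNT)
            else:  # xz
                zsel = _clamped_range(zs0 - r, zs1 + r, nz)
                xsel = _clamped_range(-r, nx + r, nx)
                cp = codes[np.ix_(zsel, np.arange(ny), xsel)]
                for y in range(ny):
                    out[:, y, :, sl] = _window_hist_2d(cp[:, y, :], r, LBP_CODE_COUNT)
        return out

    def _upsample(
        self, level_arr: np.ndarray, z0: int, z1: int, zs0: int, s: int
    ) -> np.ndarray:
        """Replicate level-scale per-voxel results back onto the scale-0 grid."""
        if s == 0:
            return level_arr
        nz0, ny0, nx0 = self.pyramid.shape
        nzs, nys, nxs = self.pyramid.level(s).shape
        f = 2 ** s
        zi = np.minimum(np.arange(z0, z1) // f, nzs - 1) - zs0
        yi = np.minimum(np.arange(ny0) // f, nys - 1)
        xi = np.minimum(np.arange(nx0) // f, nxs - 1)
        return level_arr[np.ix_(zi, yi, xi)]

    def block_features(
        self, z0: int, z1: int, config: FeatureConfig, normalise: bool = True
    ) -> np.ndarray:
        """Feature rows for *every* voxel with z in [z0, z1), ordered by
        (z, y, x); the production path for whole-volume segmentation."""
        nz, ny, nx = self.pyramid.shape
        n = (z1 - z0) * ny * nx
        parts = []
        if config.include_intensity:
            parts.append(
                self.pyramid.level(0)[z0:z1].astype(np.float64).reshape(n, 1)
            )
        for spec in (config.hist1, config.hist2):
            h = self.dense_histograms(z0, z1, spec).reshape(n, spec.k)
            h = h.astype(np.float64)
            if normalise:
                h /= spec.neighbourhood_size
            parts.append(h)
        l = self.dense_lbp(z0, z1, config.lbp).reshape(n, LBP_FEATURE_LENGTH)
        l = l.astype(np.float64)
        if normalise:
            l /= config.lbp.neighbourhood_size
        parts.append(l)
        return np.concatenate(parts, axis=1)


# --------------------------------------------------------------------------
# Module-level operations (thin wrappers over FeatureExtractor)
# --------------------------------------------------------------------------

def histogram_at(
    pyramid: Pyramid,
    coord: Sequence[int],
    spec: HistogramSpec,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Neighbourhood histogram counts (k-vector, sums to (2r+1)^3) of the
    cube centred at ``map_coordinate(coord, spec.s)``."""
    ext = FeatureExtractor(pyramid, bounds)
    return ext.histograms_for_coords(
        np.asarray(coord)[None, :], spec, method="gather"
    )[0]


def slab_histograms(
    pyramid: Pyramid,
    slab: SlabView,
    spec: HistogramSpec,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-voxel histogram counts for every voxel in the slab's z_range,
    computed with the incremental plane-update algorithm.

    Identical, voxel for voxel, to calling :func:`histogram_at` on each
    coordinate independently.
    """
    required = spec.r * 2 ** spec.s
    if slab.halo < required:
        raise ValueError(
            f"slab halo {slab.halo} insufficient: radius {spec.r} at scale "
            f"{spec.s} needs a halo of {required} scale-0 slices"
        )
    ext = FeatureExtractor(pyramid, bounds)
    z0, z1 = slab.z_range
    return ext.dense_histograms(z0, z1, spec)


def lbp_plane_histogram(
    level: np.ndarray, coord: Sequence[int], plane: str, r: int
) -> np.ndarray:
    """Histogram (10-vector, sums to (2r+1)^2) of LBP codes in the 2D
    radius-``r`` window around ``coord`` in the given orthogonal plane
    of a single pyramid level."""
    level = np.asarray(level)
    z, y, x = (int(c) for c in coord)
    if plane == "xy":
        codes = plane_codes(level[z])
        cc = (y, x)
    elif plane == "yz":
        codes = plane_codes(level[:, :, x])
        cc = (z, y)
    elif plane == "xz":
        codes = plane_codes(level[:, y, :])
        cc = (z, x)
    else:
        raise ValueError(f"plane must be one of {LBP_PLANES}, got {plane!r}")
    h, w = codes.shape
    rows = _clamped_range(cc[0] - r, cc[0] + r + 1, h)
    cols = _clamped_range(cc[1] - r, cc[1] + r + 1, w)
    window = codes[np.ix_(rows, cols)]
    return np.bincount(window.ravel(), minlength=LBP_CODE_COUNT).astype(np.int64)


def lbp_top_feature(
    pyramid: Pyramid, coord: Sequence[int], spec: LBPSpec
) -> np.ndarray:
    """Concatenated xy | yz | xz LBP code histograms (30-vector) at the
    mapped coordinate of the requested scale."""
    ext = FeatureExtractor(pyramid)
    return ext.lbp_for_coords(np.asarray(coord)[None, :], spec)[0]


def compose_features(
    pyramid: Pyramid,
    coords: np.ndarray,
    config: FeatureConfig,
    normalise: bool = True,
    bounds: tuple[float, float] | None = None,
) -> FeatureMatrix:
    """Feature matrix for the given scale-0 coordinates, one row each, in
    the canonical [intensity | hist1 | hist2 | lbp] column layout.

    Histogram blocks are divided by their neighbourhood sizes when
    ``normalise`` is set (the default used for classification); raw
    counts are available for testing with ``normalise=False``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
    ext = FeatureExtractor(pyramid, bounds)
    rows = ext.features_for_coords(coords, config, normalise=normalise)
    return FeatureMatrix(rows=rows, row_coords=coords, config=config)
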