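"""Synthetic labelled multi-texture volumes for testing and demos.

Regions differ both in intensity distribution (separable by
neighbourhood histograms) and in spatial texture (separable only by
LBP), so every stage of the segmenter is exercisable without any
external scan.  Generators are pure functions of (spec, shape, seed):
intensities are drawn in the unit interval and quantised to 16 bits so
the integer I/O path is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from voxelseg.volume import AnnotatedSlice, LabelMap, Volume


@dataclass(frozen=True)
class TextureRegionSpec:
    """One labelled region: a geometry plus an intensity model.

    Geometry kinds: ``halfspace`` (axis, frac, side), ``sphere``
    (center_frac, radius_frac), ``shell`` (center_frac, r0_frac,
    r1_frac), ``rest`` (complement of all other regions).

    Intensity kinds: ``gaussian`` (mean, sigma), ``smoothed_noise``
    (mean, sigma, corr_len), ``stripes`` (mean, period, axis, contrast,
    sigma).
    """

    name: str
    geometry: dict
    intensity: dict


def _geometry_mask(geom: dict, shape: tuple[int, int, int]) -> np.ndarray | None:
    kind = geom["kind"]
    if kind == "rest":
        return None
    if kind == "halfspace":
        axis = geom["axis"]
        cut = int(round(geom["frac"] * shape[axis]))
        idx = np.arange(shape[axis])
        line = idx < cut if geom.get("side", "low") == "low" else idx >= cut
        reshape = [1, 1, 1]
        reshape[axis] = shape[axis]
        return np.broadcast_to(line.reshape(reshape), shape).copy()
    if kind in ("sphere", "shell"):
        center = geom.get("center_frac", (0.5, 0.5, 0.5))
        grids = np.meshgrid(
            *[np.arange(n) - c * (n - 1) for n, c in zip(shape, center)],
            indexing="ij",
        )
        d = np.sqrt(sum(g ** 2 for g in grids))
        ref = min(shape)
        if kind == "sphere":
            return d < geom["radius_frac"] * ref
        return (d >= geom["r0_frac"] * ref) & (d < geom["r1_frac"] * ref)
    raise ValueError(f"unknown geometry kind {kind!r}")


def _intensity_field(
    model: dict, shape: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    kind = model["kind"]
    if kind == "gaussian":
        return rng.normal(model["mean"], model["sigma"], size=shape)
    if kind == "smoothed_noise":
        field = gaussian_filter(
            rng.standard_normal(shape), sigma=model["corr_len"], mode="reflect"
        )
        field /= field.std() or 1.0
        return model["mean"] + model["sigma"] * field
    if kind == "stripes":
        axis = model.get("axis", 2)
        coord = np.arange(shape[axis], dtype=np.float64)
        wave = np.sin(2 * np.pi * coord / model["period"])
        reshape = [1, 1, 1]
        reshape[axis] = shape[axis]
        base = model["mean"] + model["contrast"] * wave.reshape(reshape)
        return base + rng.normal(0.0, model["sigma"], size=shape)
    raise ValueError(f"unknown intensity kind {kind!r}")


def _quantise(unit_values: np.ndarray) -> np.ndarray:
    clipped = np.clip(unit_values, 0.0, 1.0)
    return np.round(clipped * 65535).astype(np.uint16)


def make_textured_volume(
    specs: Sequence[TextureRegionSpec],
    shape: tuple[int, int, int],
    seed: int = 0,
) -> tuple[Volume, np.ndarray]:
    """Build a labelled volume whose regions partition every voxel.

    Region label ids follow the order of ``specs``.  Overlapping
    geometries are an error; at most one ``rest`` region absorbs the
    complement.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(n) for n in shape)
    if min(shape) < 16:
        raise ValueError("shape must be at least 16 in every dimension")
    rng = np.random.default_rng(seed)

    masks: list[np.ndarray | None] = [
        _geometry_mask(s.geometry, shape) for s in specs
    ]
    rest_idx = [i for i, m in enumerate(masks) if m is None]
    if len(rest_idx) > 1:
        raise ValueError("at most one 'rest' region is allowed")
    explicit = [m for m in masks if m is not None]
    cover = np.zeros(shape, dtype=np.int64)
    for m in explicit:
        cover += m
    if cover.max() > 1:
        raise ValueError("region geometries overlap")
    if rest_idx:
        masks[rest_idx[0]] = cover == 0
    elif not (cover == 1).all():
        raise ValueError("region geometries do not cover the volume")

    labels = np.zeros(shape, dtype=np.uint8)
    data = np.zeros(shape, dtype=np.float64)
    for lid, (spec, mask) in enumerate(zip(specs, masks)):
        field = _intensity_field(spec.intensity, shape, rng)
        data[mask] = field[mask]
        labels[mask] = lid
    return Volume(_quantise(data)), labels


# --------------------------------------------------------------------------
# Canned fixtures
# --------------------------------------------------------------------------

def three_region_specs() -> list[TextureRegionSpec]:
    """Default fixture: striped wrapping shell, smoothed-noise soft
    tissue, bright bone core — distinct means several sigma apart plus
    distinct spatial textures."""
    return [
        TextureRegionSpec(
            name="wrapping",
            geometry={"kind": "rest"},
            intensity={"kind": "stripes", "mean": 0.25, "period": 6.0,
                       "axis": 2, "contrast": 0.10, "sigma": 0.02},
        ),
        TextureRegionSpec(
            name="soft_tissue",
            geometry={"kind": "shell", "r0_frac": 0.22, "r1_frac": 0.42},
            intensity={"kind": "smoothed_noise", "mean": 0.52, "sigma": 0.04,
                       "corr_len": 1.5},
        ),
        TextureRegionSpec(
            name="bone",
            geometry={"kind": "sphere", "radius_frac": 0.22},
            intensity={"kind": "gaussian", "mean": 0.82, "sigma": 0.03},
        ),
    ]


def three_region_label_map() -> LabelMap:
    return LabelMap(("wrapping", "soft_tissue", "bone"), unlabelled_id=0)


def make_three_region_volume(
    shape: tuple[int, int, int] = (64, 64, 64), seed: int = 0
) -> tuple[Volume, np.ndarray, LabelMap]:
    vol, labels = make_textured_volume(three_region_specs(), shape, seed)
    return vol, labels, three_region_label_map()


def make_lbp_discriminable_pair(
    shape: tuple[int, int, int] = (32, 32, 32), seed: int = 0
) -> tuple[Volume, np.ndarray, LabelMap]:
    """Two regions with matched intensity statistics but different
    spatial structure.

    Both regions are Gaussian noise smoothed with the *same* width but
    along orthogonal in-slice axes (label 0 along y, label 1 along x).
    The labels tile each slice as a 2x2 checkerboard of quadrants,
    making the two textures exact mirror ensembles (transpose + mirror
    maps one onto the other, quadrant boundaries included), so
    cube-shaped neighbourhood histograms carry no label signal.  On top
    of that, label 1's values are rank-matched onto label 0's empirical
    value distribution, so the two regions share an identical multiset
    of intensities and even realisation-level histogram quirks cancel.
    The orientation of the correlation remains plainly visible to the
    three-orthogonal-plane LBP blocks (the yz and xz blocks swap roles
    between the labels).
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 in every dimension")
    rng = np.random.default_rng(seed)
    mean, sigma = 0.5, 0.08
    sigma_smooth = 1.5

    along_y = gaussian_filter1d(
        rng.standard_normal(shape), sigma=sigma_smooth, axis=1, mode="wrap"
    )
    along_x = gaussian_filter1d(
        rng.standard_normal(shape), sigma=sigma_smooth, axis=2, mode="wrap"
    )

    cy, cx = shape[1] // 2, shape[2] // 2
    upper, right = np.meshgrid(
        np.arange(shape[1]) >= cy, np.arange(shape[2]) >= cx, indexing="ij"
    )
    mask1 = np.broadcast_to(upper ^ right, shape)
    labels = mask1.astype(np.uint8)

    v0 = along_y[~mask1]
    v0 = mean + sigma * (v0 - v0.mean()) / v0.std()
    v1 = along_x[mask1]
    order = np.argsort(v1, kind="stable")
    matched = np.empty_like(v1)
    matched[order] = np.sort(v0)  # identical value multiset for both labels
    data = np.empty(shape)
    data[~mask1] = v0
    data[mask1] = matched
    label_map = LabelMap(("stripes_y", "stripes_x"), unlabelled_id=0)
    return Volume(_quantise(data)), labels, label_map


def annotations_from_labels(
    label_volume: np.ndarray, z_indices: Sequence[int]
) -> list[AnnotatedSlice]:
    """Fully annotated truth slices extracted from a label volume."""
    return [
        AnnotatedSlice(int(z), label_volume[int(z)].astype(np.uint8))
        for z in z_indices
    ]


def evenly_spaced_slices(nz: int, n: int) -> list[int]:
    """n distinct z indices spread evenly through the volume."""
    return sorted(set(int(round(z)) for z in np.linspace(0, nz - 1, n)))
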