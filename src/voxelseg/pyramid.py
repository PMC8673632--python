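"""Multi-scale volume representation: Gaussian blur then decimate by 2^s.

Level 0 is the original data untouched.  Level ``s`` is obtained by
blurring the *scale-0* volume with a Gaussian of width ``sigma_rule(s)``
(default ``2**(s-1)`` voxels, a standard anti-alias width proportional
to the decimation factor) and keeping every ``2**s``-th voxel starting
at index 0.  Blur uses reflect padding so volume faces do not darken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from voxelseg.volume import Volume


def default_sigma_rule(s: int) -> float:
    """Anti-alias blur width (in scale-0 voxels) before decimating by 2^s."""
    return 0.0 if s == 0 else float(2 ** (s - 1))


def map_coordinate(coord: Sequence[int], s: int) -> tuple[int, ...]:
    """Map a scale-0 coordinate to scale ``s`` by floor division by 2^s."""
    f = 2 ** s
    return tuple(int(c) // f for c in coord)


@dataclass
class Pyramid:
    """Volume levels for scales ``0..S_max`` plus the scale-0 intensity bounds.

    Levels beyond 0 are float64 (blurred); binning downstream always uses
    the recorded scale-0 bounds so blurred values (which can only
    interpolate) are clamped into the end bins.
    """

    levels: list[np.ndarray]
    intensity_min: float
    intensity_max: float
    sigma_rule: Callable[[int], float] = field(default=default_sigma_rule)

    @property
    def S_max(self) -> int:
        return len(self.levels) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.levels[0].shape)  # type: ignore[return-value]

    def level(self, s: int) -> np.ndarray:
        if not 0 <= s <= self.S_max:
            raise ValueError(f"scale {s} outside pyramid (S_max={self.S_max})")
        return self.levels[s]


def save_pyramid(pyramid: Pyramid, path, dataset_prefix: str = "/scale_") -> None:
    """Cache pyramid levels to HDF5 (``/scale_0``, ``/scale_1``, ...)."""
    import h5py

    with h5py.File(path, "w") as f:
        for s, level in enumerate(pyramid.levels):
            f.create_dataset(f"{dataset_prefix}{s}", data=level)
        f.attrs["intensity_min"] = pyramid.intensity_min
        f.attrs["intensity_max"] = pyramid.intensity_max


def load_pyramid(path, dataset_prefix: str = "/scale_") -> Pyramid:
    """Load a pyramid previously written by :func:`save_pyramid`."""
    import h5py

    with h5py.File(path, "r") as f:
        levels = []
        while f"{dataset_prefix}{len(levels)}" in f:
            levels.append(f[f"{dataset_prefix}{len(levels)}"][()])
        if not levels:
            raise ValueError(f"no pyramid levels found in {path}")
        return Pyramid(
            levels=levels,
            intensity_min=float(f.attrs["intensity_min"]),
            intensity_max=float(f.attrs["intensity_max"]),
        )


def build_pyramid(
    volume: Volume,
    S_max: int,
    sigma_rule: Callable[[int], float] = default_sigma_rule,
) -> Pyramid:
    """Build levels 0..S_max, each blurred from scale 0 then decimated.

    Every volume dimension must be at least ``2**S_max`` so each level
    keeps all components >= 1.
    """
    if S_max < 0:
        raise ValueError("S_max must be >= 0")
    shape = volume.shape
    for axis, n in zip("zyx", shape):
        if n < 2 ** S_max:
            raise ValueError(
                f"axis {axis} has size {n} < 2**S_max = {2 ** S_max}; "
                "reduce S_max or enlarge the volume"
            )
    levels: list[np.ndarray] = [volume.data]
    if S_max > 0:
        base = volume.data.astype(np.float64)
        for s in range(1, S_max + 1):
            sigma = sigma_rule(s)
            blurred = (
                gaussian_filter(base, sigma=sigma, mode="reflect", truncate=4.0)
                if sigma > 0 else base
            )
            step = 2 ** s
            dec = blurred[::step, ::step, ::step]
            # floor shape convention: drop the trailing partial block
            levels.append(np.ascontiguousarray(
                dec[: shape[0] // step, : shape[1] // step, : shape[2] // step]
            ))
    return Pyramid(
        levels=levels,
        intensity_min=volume.intensity_min,
        intensity_max=volume.intensity_max,
        sigma_rule=sigma_rule,
    )
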