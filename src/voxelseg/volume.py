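"""Volume and label-slice I/O plus memory-bounded slab access.

Axis convention is ``(z, y, x)`` with ``z`` the slice index; all
coordinates are 0-based and z-ranges are half-open.  Volumes are read
from a directory of equally shaped 2D TIFF slices (lexicographic
filename order = z order), a single multi-page TIFF, or an HDF5 dataset.
Label slices are integer-coded PNG/TIFF images whose filename encodes
the z index (``labels_z00042.png``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import tifffile
import imageio.v3 as iio

#: Sentinel value for voxels carrying no manual annotation.  Fixed at the
#: top of the 8-bit range so it never collides with small label counts.
IGNORE_ID = 255

_INT_DTYPES = (np.uint8, np.uint16)

_Z_PATTERN = re.compile(r"z(\d+)\D*$")


class VolumeFormatError(ValueError):
    """Raised for malformed or unsupported volume/label files."""


def _check_dtype(data: np.ndarray) -> None:
    if data.dtype.type in _INT_DTYPES:
        return
    if np.issubdtype(data.dtype, np.floating):
        if data.size and (data.min() < 0.0 or data.max() > 1.0):
            raise VolumeFormatError(
                "floating-point volumes must lie in the unit interval "
                f"[0, 1]; got range [{data.min()}, {data.max()}]"
            )
        return
    raise VolumeFormatError(
        f"unsupported volume dtype {data.dtype!r}: expected uint8, uint16 "
        "or unit-interval float"
    )


@dataclass
class Volume:
    """A 3D grid of scalar intensities with recorded global bounds.

    ``intensity_min``/``intensity_max`` are fixed at construction and are
    the reference range for histogram binning everywhere downstream.
    """

    data: np.ndarray
    intensity_min: float = field(default=None)  # type: ignore[assignment]
    intensity_max: float = field(default=None)  # type: ignore[assignment]
    voxel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume must be 3D (z, y, x); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError(f"empty volume axis in shape {self.data.shape}")
        _check_dtype(self.data)
        if self.intensity_min is None:
            self.intensity_min = float(self.data.min())
        if self.intensity_max is None:
            self.intensity_max = float(self.data.max())
        if self.intensity_min > self.intensity_max:
            raise VolumeFormatError("intensity_min exceeds intensity_max")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class LabelMap:
    """Ordered label names with contiguous ids ``0..N-1``.

    ``unlabelled_id`` is the explicit "anything else" class (a trainable
    label); ``ignore_id`` marks voxels with no manual annotation at all
    and never appears among the ids.
    """

    names: tuple[str, ...]
    unlabelled_id: int = 0
    ignore_id: int = IGNORE_ID

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 2:
            raise ValueError("a label map needs at least 2 labels")
        if len(set(self.names)) != len(self.names):
            raise ValueError("label names must be unique")
        if not 0 <= self.unlabelled_id < len(self.names):
            raise ValueError("unlabelled_id must be one of the label ids")
        if self.ignore_id in self.ids:
            raise ValueError("ignore_id must not collide with a label id")

    @property
    def ids(self) -> range:
        return range(len(self.names))

    @property
    def n_labels(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "unlabelled_id": self.unlabelled_id,
            "ignore_id": self.ignore_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelMap":
        return cls(tuple(d["names"]), d["unlabelled_id"], d["ignore_id"])


@dataclass
class AnnotatedSlice:
    """A 2D grid of label ids (or ignore_id) aligned to one z slice."""

    slice_index: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise VolumeFormatError("annotated slice must be a 2D label image")

    def label_counts(self, label_map: LabelMap) -> dict[int, int]:
        """Per-label voxel counts, excluding ignore voxels."""
        out = {}
        for lid in label_map.ids:
            n = int(np.count_nonzero(self.labels == lid))
            if n:
                out[lid] = n
        return out


@dataclass
class SlabView:
    """A contiguous half-open z-range plus halo slices loaded around it.

    ``data`` spans ``loaded_range`` (the z-range extended by the clamped
    halo); output voxels belong to ``z_range`` only, so slabs tile the
    volume without gaps or double counting.
    """

    z_range: tuple[int, int]
    halo: int
    data: np.ndarray
    loaded_range: tuple[int, int]

    @property
    def thickness(self) -> int:
        return self.z_range[1] - self.z_range[0]


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def read_volume(
    path: str | Path,
    format: str | None = None,
    dataset: str = "/volume",
    voxel_size_um: float | None = None,
) -> Volume:
    """Read a volume from a TIFF slice directory, multi-page TIFF or HDF5.

    Format is inferred from the path when not given: a directory is read
    as a TIFF slice stack, ``.h5``/``.hdf5`` as HDF5 (dataset name
    configurable), anything else through tifffile.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "stack"
        elif path.suffix.lower() in (".h5", ".hdf5"):
            format = "hdf5"
        else:
            format = "tiff"

    if format == "stack":
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise VolumeFormatError(f"no TIFF slices found in {path}")
        slices = []
        shape = None
        for f in files:
            img = tifffile.imread(f)
            if img.ndim != 2:
                raise VolumeFormatError(f"slice {f.name} is not 2D")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise VolumeFormatError(
                    f"inconsistent slice shapes: {f.name} has {img.shape}, "
                    f"expected {shape}"
                )
            slices.append(img)
        data = np.stack(slices, axis=0)
    elif format == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            data = f[dataset][()]
    else:
        raise ValueError(f"unknown volume format {format!r}")
    return Volume(data, voxel_size_um=voxel_size_um)


def write_volume(
    volume: Volume,
    path: str | Path,
    format: str | None = None,
    dataset: str = "/volume",
) -> None:
    """Write a volume as a TIFF slice stack, multi-page TIFF or HDF5."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() in (".h5", ".hdf5"):
            format = "hdf5"
        elif path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff"
        else:
            format = "stack"

    if format == "stack":
        path.mkdir(parents=True, exist_ok=True)
        width = max(5, len(str(volume.nz - 1)))
        for z in range(volume.nz):
            tifffile.imwrite(path / f"slice_z{z:0{width}d}.tif", volume.data[z])
    elif format == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, volume.data)
    elif format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=volume.data)
    else:
        raise ValueError(f"unknown volume format {format!r}")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _z_from_name(path: Path) -> int:
    m = _Z_PATTERN.search(path.stem + path.suffix)
    if m is None:
        raise VolumeFormatError(
            f"cannot parse z index from label filename {path.name!r}; "
            "expected something like labels_z00042.png"
        )
    return int(m.group(1))


def read_annotations(
    paths: Sequence[str | Path],
    label_map: LabelMap,
    volume_shape: tuple[int, int, int] | None = None,
) -> list[AnnotatedSlice]:
    """Read integer-coded label slices and validate against the label map.

    Every non-ignore code must be a valid label id; the slice shape must
    match the volume's ``(ny, nx)`` when a shape is supplied.
    """
    out = []
    for p in paths:
        p = Path(p)
        z = _z_from_name(p)
        img = np.asarray(iio.imread(p))
        if img.ndim != 2:
            raise VolumeFormatError(f"label image {p.name} is not 2D")
        if volume_shape is not None:
            if img.shape != tuple(volume_shape[1:]):
                raise VolumeFormatError(
                    f"label image {p.name} shape {img.shape} does not match "
                    f"volume (ny, nx) {tuple(volume_shape[1:])}"
                )
            if not 0 <= z < volume_shape[0]:
                raise VolumeFormatError(
                    f"label slice z={z} outside volume of {volume_shape[0]} slices"
                )
        codes = np.unique(img)
        bad = [int(c) for c in codes
               if int(c) != label_map.ignore_id and int(c) not in label_map.ids]
        if bad:
            raise VolumeFormatError(
                f"label image {p.name} contains codes {bad} not in the label "
                f"map (valid ids 0..{label_map.n_labels - 1}, "
                f"ignore={label_map.ignore_id})"
            )
        out.append(AnnotatedSlice(z, img.astype(np.uint8)))
    out.sort(key=lambda s: s.slice_index)
    return out


def write_annotation(labels: np.ndarray, z: int, directory: str | Path) -> Path:
    """Write one label slice as ``labels_z{z:05d}.png``; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"labels_z{z:05d}.png"
    iio.imwrite(path, np.asarray(labels, dtype=np.uint8))
    return path


# ---------------------------------------------------------------------------
# Slab access
# ---------------------------------------------------------------------------

def iter_slabs(
    volume: Volume, slab_thickness: int, halo: int = 0
) -> Iterator[SlabView]:
    """Tile the z axis into slabs of ``slab_thickness`` with clamped halos.

    The union of z_ranges is exactly ``[0, nz)`` with no overlap.  Halo
    slices beyond the volume are clamped away (with a warning when the
    halo cannot be fully honoured anywhere).
    """
    if slab_thickness < 1:
        raise ValueError("slab_thickness must be >= 1")
    if halo < 0:
        raise ValueError("halo must be >= 0")
    nz = volume.nz
    if halo >= nz:
        warnings.warn(
            f"halo {halo} is not smaller than the volume ({nz} slices); "
            "halos will be clamped",
            stacklevel=2,
        )
    for z0 in range(0, nz, slab_thickness):
        z1 = min(z0 + slab_thickness, nz)
        lo = max(0, z0 - halo)
        hi = min(nz, z1 + halo)
        yield SlabView(
            z_range=(z0, z1),
            halo=halo,
            data=volume.data[lo:hi],
            loaded_range=(lo, hi),
        )
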