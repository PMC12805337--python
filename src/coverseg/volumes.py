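"""Domain types, coordinate conventions, and volume I/O for volume EM data.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` in storage — z is the (possibly anisotropic)
  section axis of serial-section EM;
* indices are 0-based and windows are half-open, so crops tile exactly;
* instance id 0 is the background / ignore label everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple, Union

import h5py
import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "InstanceVolume",
    "SubVolumeSpec",
    "DatasetRole",
    "read_volume",
    "write_volume",
    "crop",
]


@dataclass
class Volume3D:
    """A real-valued intensity grid of shape (D, H, W), normalized to [0, 1].

    Attributes
    ----------
    data : ndarray
        float array, axis order (z, y, x).
    voxel_size : tuple of float, optional
        Physical voxel size per axis in nm, (z, y, x).
    """

    data: np.ndarray
    voxel_size: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D grid, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all axes must have extent >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1] after normalization")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class InstanceVolume:
    """A dense instance-id grid of shape (D, H, W); id 0 is background/ignore."""

    ids: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 3:
            raise ValueError(f"InstanceVolume requires a 3-D grid, got ndim={self.ids.ndim}")
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValueError("instance ids must be integers")
        if self.ids.min() < 0:
            raise ValueError("instance ids must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.ids.shape


@dataclass(frozen=True)
class SubVolumeSpec:
    """A half-open axis-aligned window: voxels origin <= p < origin + size."""

    origin: Tuple[int, int, int]
    size: Tuple[int, int, int]

    def __post_init__(self):
        if len(self.origin) != 3 or len(self.size) != 3:
            raise ValueError("origin and size must be 3-tuples (z, y, x)")
        if any(o < 0 for o in self.origin) or any(s < 1 for s in self.size):
            raise ValueError("origin must be >= 0 and size >= 1 per axis")

    @property
    def end(self) -> Tuple[int, int, int]:
        return tuple(o + s for o, s in zip(self.origin, self.size))

    def within(self, shape: Tuple[int, int, int]) -> bool:
        return all(e <= s for e, s in zip(self.end, shape))

    def overlaps(self, other: "SubVolumeSpec") -> bool:
        return all(
            o1 < e2 and o2 < e1
            for o1, e1, o2, e2 in zip(self.origin, self.end, other.origin, other.end)
        )

    def to_json(self) -> str:
        return json.dumps({"origin": list(self.origin), "size": list(self.size)})

    @classmethod
    def from_json(cls, text: str) -> "SubVolumeSpec":
        d = json.loads(text)
        return cls(tuple(d["origin"]), tuple(d["size"]))


class DatasetRole(Enum):
    """Role of a configured volume in the pipeline."""

    UNLABELED = "unlabeled"  # D_u: pool for selection and consistency training
    LABELED = "labeled"      # D_l: annotated sub-volumes
    TEST = "test"


_LABEL_DTYPES = (np.uint16, np.uint32, np.uint64, np.int16, np.int32, np.int64)


def _normalize_intensity(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if lo < 0.0 or hi > 1.0:
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return arr


def read_volume(
    path: Union[str, Path],
    key: str = "raw",
    kind: Optional[str] = None,
) -> Union[Volume3D, InstanceVolume]:
    """Read a 3-D volume from HDF5 (by dataset key) or a multi-page TIFF stack.

    The returned type follows ``kind`` ("raw" or "labels") when given;
    otherwise the dataset key "labels" or an integer label dtype
    (uint16/32/64, signed ints) yields an :class:`InstanceVolume`, while
    uint8 / float data yields a :class:`Volume3D` normalized to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path))
    else:
        with h5py.File(path, "r") as f:
            if key not in f:
                raise KeyError(f"dataset {key!r} not found in {path}")
            arr = f[key][()]
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D array, got shape {arr.shape}")
    if kind is not None:
        as_labels = kind == "labels"
    elif key == "labels":
        as_labels = True
    elif key == "raw":
        as_labels = False
    else:
        as_labels = arr.dtype in [np.dtype(t) for t in _LABEL_DTYPES]
    if as_labels:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("label volumes must have an integer dtype")
        return InstanceVolume(arr.astype(np.int64))
    return Volume3D(_normalize_intensity(arr))


def write_volume(
    vol: Union[Volume3D, InstanceVolume],
    path: Union[str, Path],
    key: Optional[str] = None,
) -> None:
    """Write a volume to HDF5 ("raw" float32 / "labels" uint64) or TIFF."""
    path = Path(path)
    if isinstance(vol, InstanceVolume):
        key = key or "labels"
        arr = vol.ids.astype(np.uint64)
    else:
        key = key or "raw"
        arr = vol.data.astype(np.float32)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
        return
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        f.create_dataset(key, data=arr)


def crop(
    vol: Union[Volume3D, InstanceVolume], spec: SubVolumeSpec
) -> Union[Volume3D, InstanceVolume]:
    """Extract the half-open window ``spec`` from a volume (copy)."""
    shape = vol.shape
    if not spec.within(shape):
        raise ValueError(f"crop window {spec} exceeds volume shape {shape}")
    sl = tuple(slice(o, e) for o, e in zip(spec.origin, spec.end))
    if isinstance(vol, InstanceVolume):
        return InstanceVolume(vol.ids[sl].copy())
    return Volume3D(vol.data[sl].copy(), voxel_size=vol.voxel_size)
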