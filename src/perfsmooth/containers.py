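"""In-memory containers for volumes, masks and dynamic series.

All grids are numpy arrays indexed ``(x, y, z)`` (series: ``(x, y, z, t)``);
physical voxel sizes are carried alongside in millimetres.  Masks are boolean
grids on the same voxel lattice as the volume they pair with.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, InvalidParameterError

Triple = tuple[float, float, float]


def as_triple(value: float | Sequence[float], name: str = "value") -> Triple:
    """Broadcast a scalar to three axes, or validate a length-3 sequence."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise InvalidParameterError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return float(arr[0]), float(arr[1]), float(arr[2])


def _check_voxel_size(voxel_size_mm: Triple) -> Triple:
    vs = as_triple(voxel_size_mm, "voxel_size_mm")
    if any(v <= 0 for v in vs):
        raise InvalidParameterError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass(frozen=True)
class Volume3D:
    """A scalar 3D image (HU or arbitrary intensity) with voxel sizes in mm.

    NaN values are permitted only to represent the explicit ``missing``
    outside-mask policy of masked smoothing; operations that require finite
    input check for it and raise :class:`~perfsmooth.errors.DataError`.
    """

    values: np.ndarray
    voxel_size_mm: Triple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise DataError(f"Volume3D requires a 3D grid, got ndim={arr.ndim}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "voxel_size_mm", _check_voxel_size(self.voxel_size_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean 3D grid aligned with a :class:`Volume3D`."""

    values: np.ndarray
    voxel_size_mm: Triple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise DataError(f"BinaryMask requires a 3D grid, got ndim={arr.ndim}")
        object.__setattr__(self, "values", arr.astype(bool))
        object.__setattr__(self, "voxel_size_mm", _check_voxel_size(self.voxel_size_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class VolumeSeries:
    """A dynamic (4D) series: ``frames[x, y, z, t]`` with frame times in s."""

    frames: np.ndarray
    voxel_size_mm: Triple = (1.0, 1.0, 1.0)
    frame_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 4:
            raise DataError(f"VolumeSeries requires a 4D grid, got ndim={arr.ndim}")
        times = self.frame_times_s
        if times is None:
            times = np.arange(arr.shape[3], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (arr.shape[3],):
            raise DataError(
                f"frame_times_s length {times.shape} does not match {arr.shape[3]} frames"
            )
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DataError("frame times must be strictly increasing")
        if not np.all(np.isfinite(arr)):
            raise DataError("series contains non-finite values")
        object.__setattr__(self, "frames", arr)
        object.__setattr__(self, "frame_times_s", times)
        object.__setattr__(self, "voxel_size_mm", _check_voxel_size(self.voxel_size_mm))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[:3]  # type: ignore[return-value]

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.frames[..., t], self.voxel_size_mm)


def require_same_grid(a, b, what: str = "grids") -> None:
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if tuple(sa)[:3] != tuple(sb)[:3]:
        raise DataError(f"{what} have mismatched shapes: {tuple(sa)} vs {tuple(sb)}")
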