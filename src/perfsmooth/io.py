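"""NIfTI volume/series I/O, line profiles, summary tables and provenance.

Volumes and masks travel as NIfTI (``.nii`` / ``.nii.gz``); masks are stored
as 8-bit integers.  Frame times for a 4D series come from a JSON sidecar
(``series.json`` next to ``series.nii.gz`` holding ``{"frame_times_s":
[...]}``) or, failing that, a uniform frame interval (default 3 s, the usual
CT-perfusion spacing).  Every file written by the CLI is accompanied by a
``<file>.provenance.json`` record of the command parameters, seed and
package version so runs are reproducible.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BinaryMask, Volume3D, VolumeSeries
from .errors import DataError, InvalidParameterError
from .simulation import SimulationSummary, summaries_to_frame

DEFAULT_FRAME_INTERVAL_S = 3.0


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(
    path: str | Path, frame_interval_s: float | None = None
) -> Volume3D | VolumeSeries:
    """Load a NIfTI file as a :class:`Volume3D` (3D) or :class:`VolumeSeries` (4D)."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
    except FileNotFoundError:
        raise DataError(f"no such file: {path}") from None
    except Exception as exc:  # nibabel raises several error types for bad files
        raise DataError(f"could not read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if data.ndim == 3:
        return Volume3D(data, voxel_size)
    if data.ndim == 4:
        times = _frame_times(path, data.shape[3], frame_interval_s)
        return VolumeSeries(data, voxel_size, times)
    raise DataError(f"{path}: expected a 3D or 4D image, got ndim={data.ndim}")


def _frame_times(path: Path, n_frames: int, frame_interval_s: float | None) -> np.ndarray:
    sidecar = _sidecar_path(path)
    if frame_interval_s is None and sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        times = np.asarray(meta.get("frame_times_s", []), dtype=float)
        if times.size != n_frames:
            raise DataError(
                f"{sidecar}: frame_times_s has {times.size} entries for {n_frames} frames"
            )
        return times
    interval = DEFAULT_FRAME_INTERVAL_S if frame_interval_s is None else frame_interval_s
    if interval <= 0:
        raise InvalidParameterError(f"frame interval must be positive, got {interval}")
    return np.arange(n_frames, dtype=float) * interval


def read_mask(path: str | Path) -> BinaryMask:
    """Load a NIfTI mask; any nonzero voxel is True."""
    volume = read_volume(path)
    if not isinstance(volume, Volume3D):
        raise DataError(f"{path}: masks must be 3D")
    return BinaryMask(volume.values != 0, volume.voxel_size_mm)


def read_labels(path: str | Path) -> np.ndarray:
    """Load a NIfTI label image as an integer grid."""
    volume = read_volume(path)
    if not isinstance(volume, Volume3D):
        raise DataError(f"{path}: label images must be 3D")
    return np.rint(volume.values).astype(int)


def write_volume(obj: Volume3D | BinaryMask | VolumeSeries, path: str | Path) -> Path:
    """Write a volume, mask or series to NIfTI (masks as 8-bit {0,1})."""
    path = Path(path)
    if isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    elif isinstance(obj, Volume3D):
        data = obj.values
    elif isinstance(obj, VolumeSeries):
        data = obj.frames
    else:
        raise InvalidParameterError(f"cannot write object of type {type(obj).__name__}")
    affine = np.diag([*obj.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = (*obj.voxel_size_mm, 1.0)[: data.ndim]
    img.header.set_zooms(zooms)
    nib.save(img, path)
    if isinstance(obj, VolumeSeries):
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"frame_times_s": obj.frame_times_s.tolist()}, fh)
    return path


def line_profile(
    volume: Volume3D, start: Sequence[int], end: Sequence[int]
) -> pd.DataFrame:
    """Sample voxel values along a line; positions in mm from the start voxel.

    Axis-aligned lines return exactly the row of voxel values; oblique lines
    are sampled at nearest-voxel steps (Bresenham-style parametrization along
    the dominant axis).
    """
    start = np.asarray(start, dtype=int)
    end = np.asarray(end, dtype=int)
    shape = np.asarray(volume.shape)
    for point, label in ((start, "start"), (end, "end")):
        if point.shape != (3,) or np.any(point < 0) or np.any(point >= shape):
            raise InvalidParameterError(f"{label} voxel {point.tolist()} outside the grid")
    delta = end - start
    n = int(np.abs(delta).max()) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = np.rint(start[None, :] + t[:, None] * delta[None, :]).astype(int)
    values = volume.values[coords[:, 0], coords[:, 1], coords[:, 2]]
    length_mm = float(np.linalg.norm(delta * np.asarray(volume.voxel_size_mm)))
    return pd.DataFrame({"position_mm": t * length_mm, "value": values})


def write_summary(
    summaries: Sequence[SimulationSummary] | pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    parameter: str = "intensity_ratio",
) -> Path:
    """Write simulation summaries as a (parameter, value, method, mean, sd, n) table."""
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        if len(summaries) == 0:
            raise InvalidParameterError("no summaries to write")
        frame = summaries_to_frame(summaries, parameter)
    if frame.empty:
        raise InvalidParameterError("no summaries to write")
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        frame.to_json(path, orient="records", indent=2)
    else:
        raise InvalidParameterError(f"unknown summary format {fmt!r}")
    return path


def write_provenance(output_path: str | Path, parameters: dict[str, Any]) -> Path:
    """Write ``<output>.provenance.json`` describing how the output was made."""
    from . import __version__

    record = {"perfsmooth_version": __version__, "parameters": _jsonable(parameters)}
    path = Path(str(output_path) + ".provenance.json")
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
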