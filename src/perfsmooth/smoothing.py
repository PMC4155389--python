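"""Simple, Removed and Masked Gaussian smoothing of 3D volumes and 4D series.

Three ways to smooth a CT volume in which a class of voxels (vessels, bone,
border) has intensities far above or below the tissue of interest:

* **Simple** -- ordinary Gaussian smoothing of the unmodified volume.  Tissue
  voxels next to a vessel are pulled toward the vessel value (upward bias).
* **Removed** -- vessel voxels are set to zero, then the volume is smoothed
  as in Simple.  Tissue voxels next to a vessel are pulled toward zero
  (downward bias, independent of the vessel intensity).
* **Masked** -- normalized convolution restricted to the tissue class: the
  class-zeroed volume and the binary class mask are each smoothed with the
  same separable kernel, and tissue voxels are set to the voxel-wise quotient

      smooth(volume * mask) / smooth(mask).

  The denominator is the sum of kernel weights (SW) that fall on same-class
  voxels, so the quotient rescales the in-class weights to unit sum.  A
  within-class constant is therefore reproduced exactly: masked smoothing is
  unbiased at class boundaries, while still averaging noise over the class.

All methods use zero padding at the grid boundary.  For masked smoothing the
padding cancels between numerator and denominator, so mask voxels near an
edge still receive the correct within-mask weighted mean.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .containers import BinaryMask, Volume3D, VolumeSeries, require_same_grid
from .errors import DataError, InternalConsistencyError, InvalidParameterError
from .kernels import KernelSpec, SeparableKernel, separable_kernel_3d

OutsidePolicy = Literal["original", "zero", "missing"]
Method = Literal["none", "simple", "removed", "masked", "multiclass"]

#: Guard for the SW denominator; can only trigger on a mask voxel via NaNs.
SW_EPS = 1e-12


@dataclass(frozen=True)
class SmoothingResult:
    """A smoothed volume together with its sum-of-weights (SW) map.

    ``sw`` is the kernel applied to the binary class mask; it is identically
    one for the Simple and Removed methods (which use no class restriction).
    """

    smoothed: Volume3D
    sw: np.ndarray
    method: str
    outside_policy: str = "original"


def _convolve_axes(values: np.ndarray, kernel: SeparableKernel) -> np.ndarray:
    out = np.asarray(values, dtype=float)
    for axis, w in enumerate(kernel.axis_weights):
        out = ndimage.convolve1d(out, w, axis=axis, mode="constant", cval=0.0)
    return out


def convolve_separable(volume: Volume3D, kernel: SeparableKernel) -> Volume3D:
    """Zero-padded separable convolution; output shape equals input shape."""
    if not np.all(np.isfinite(volume.values)):
        raise DataError("volume contains non-finite values")
    for axis, n in enumerate(kernel.lengths):
        if n > 2 * volume.shape[axis]:
            warnings.warn(
                f"kernel length {n} exceeds twice the grid extent on axis {axis}; "
                "most of the kernel falls outside the volume",
                stacklevel=2,
            )
    return Volume3D(_convolve_axes(volume.values, kernel), volume.voxel_size_mm)


def simple_smooth(volume: Volume3D, spec: KernelSpec) -> SmoothingResult:
    """Gaussian smoothing of the unmodified volume."""
    kernel = separable_kernel_3d(spec)
    smoothed = convolve_separable(volume, kernel)
    return SmoothingResult(smoothed, np.ones(volume.shape), "simple")


def removed_smooth(volume: Volume3D, vessel_mask: BinaryMask, spec: KernelSpec) -> SmoothingResult:
    """Zero the vessel voxels, then smooth as in :func:`simple_smooth`."""
    require_same_grid(volume, vessel_mask, "volume and vessel mask")
    zeroed = Volume3D(
        np.where(vessel_mask.values, 0.0, volume.values), volume.voxel_size_mm
    )
    kernel = separable_kernel_3d(spec)
    smoothed = convolve_separable(zeroed, kernel)
    return SmoothingResult(smoothed, np.ones(volume.shape), "removed")


def masked_smooth(
    volume: Volume3D,
    tissue_mask: BinaryMask,
    spec: KernelSpec,
    outside_policy: OutsidePolicy = "original",
) -> SmoothingResult:
    """Normalized convolution restricted to the mask class.

    Mask voxels receive ``smooth(volume * mask) / smooth(mask)``; voxels
    outside the mask are assigned per ``outside_policy``: their ``original``
    value (default), ``zero``, or NaN (``missing``).
    """
    require_same_grid(volume, tissue_mask, "volume and tissue mask")
    mask = tissue_mask.values
    if not mask.any():
        raise InvalidParameterError("tissue mask is empty")
    if outside_policy not in ("original", "zero", "missing"):
        raise InvalidParameterError(f"unknown outside_policy {outside_policy!r}")
    if not np.all(np.isfinite(volume.values)):
        raise DataError("volume contains non-finite values")

    kernel = separable_kernel_3d(spec)
    sw = _convolve_axes(mask.astype(float), kernel)
    numerator = _convolve_axes(np.where(mask, volume.values, 0.0), kernel)
    if np.any(sw[mask] <= SW_EPS):
        # Every mask voxel carries at least its own centre weight (> 0), so
        # this is reachable only through NaN/garbage propagation.
        raise InternalConsistencyError("sum-of-weights underflowed on a mask voxel")
    quotient = numerator / np.maximum(sw, SW_EPS)

    if outside_policy == "original":
        out = volume.values.copy()
    elif outside_policy == "zero":
        out = np.zeros(volume.shape)
    else:
        out = np.full(volume.shape, np.nan)
    out[mask] = quotient[mask]
    return SmoothingResult(Volume3D(out, volume.voxel_size_mm), sw, "masked", outside_policy)


def multiclass_smooth(volume: Volume3D, labels: np.ndarray, spec: KernelSpec) -> Volume3D:
    """Masked smoothing applied independently to each label class, composed.

    Each class is smoothed only from voxels of the same label, so a
    piecewise-constant labelled volume is reproduced exactly.
    """
    labels = np.asarray(labels)
    require_same_grid(volume, labels, "volume and labels")
    out = np.empty(volume.shape)
    for label in np.unique(labels):
        class_mask = BinaryMask(labels == label, volume.voxel_size_mm)
        if class_mask.count == 0:  # pragma: no cover - unique() precludes it
            warnings.warn(f"label {label} has no voxels; skipped", stacklevel=2)
            continue
        result = masked_smooth(volume, class_mask, spec, outside_policy="zero")
        out[class_mask.values] = result.smoothed.values[class_mask.values]
    return Volume3D(out, volume.voxel_size_mm)


def smooth_series(
    series: VolumeSeries,
    method: Method,
    spec: KernelSpec,
    tissue_mask: BinaryMask | None = None,
    vessel_mask: BinaryMask | None = None,
    labels: np.ndarray | None = None,
    outside_policy: OutsidePolicy = "original",
) -> VolumeSeries:
    """Apply one smoothing method frame-by-frame to a dynamic series.

    The masks are frame-independent (a voxel keeps its classification across
    the whole series); smoothing is purely spatial, never temporal.
    """
    if method == "none":
        return series
    frames = np.empty_like(series.frames)
    for t in range(series.n_frames):
        frame = series.frame(t)
        if method == "simple":
            frames[..., t] = simple_smooth(frame, spec).smoothed.values
        elif method == "removed":
            if vessel_mask is None:
                raise InvalidParameterError("removed smoothing requires a vessel mask")
            frames[..., t] = removed_smooth(frame, vessel_mask, spec).smoothed.values
        elif method == "masked":
            if tissue_mask is None:
                raise InvalidParameterError("masked smoothing requires a tissue mask")
            frames[..., t] = masked_smooth(
                frame, tissue_mask, spec, outside_policy
            ).smoothed.values
        elif method == "multiclass":
            if labels is None:
                raise InvalidParameterError("multiclass smoothing requires a label grid")
            frames[..., t] = multiclass_smooth(frame, labels, spec).values
        else:
            raise InvalidParameterError(f"unknown smoothing method {method!r}")
    return VolumeSeries(frames, series.voxel_size_mm, series.frame_times_s)
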