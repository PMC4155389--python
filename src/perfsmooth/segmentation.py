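"""Vessel/tissue segmentation of dynamic CT and the vessel-adjacent ROI.

Dynamic CT makes vessel identification unusually easy: a voxel's class is the
same in every frame, and contrast passage gives vascular voxels both a high
temporal mean and a large max-minus-min enhancement.  Thresholding the mean
image and the difference of the maximum and minimum images is therefore the
segmentation used here; artery/vein discrimination and skull stripping are
out of scope (the brain mask is an input, with a crude HU-band fallback).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .containers import BinaryMask, Volume3D, VolumeSeries, require_same_grid
from .errors import InvalidParameterError


@dataclass(frozen=True)
class SegmentationThresholds:
    """Thresholds for vessel identification.

    ``diff_threshold`` (HU) applies to the max-minus-min image and
    ``mean_threshold`` (HU) to the temporal mean; a voxel inside the brain
    mask is vascular if it exceeds either.  When ``diff_threshold`` is unset
    it defaults to ``enhancement_ratio`` times the median positive
    enhancement within the brain mask -- contrast makes vessels several-fold
    (by default four-fold) brighter than neighbouring tissue.
    """

    diff_threshold: float | None = None
    mean_threshold: float | None = None
    enhancement_ratio: float = 4.0

    def __post_init__(self) -> None:
        for name in ("diff_threshold", "mean_threshold"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be positive when set, got {v}")
        if self.enhancement_ratio <= 0:
            raise InvalidParameterError(
                f"enhancement_ratio must be positive, got {self.enhancement_ratio}"
            )


class SummaryImages(NamedTuple):
    mean: Volume3D
    max: Volume3D
    min: Volume3D
    diff: Volume3D


def summary_images(series: VolumeSeries) -> SummaryImages:
    """Voxel-wise temporal mean, max, min and diff (= max - min) images."""
    if series.n_frames < 2:
        raise InvalidParameterError("summary images require at least 2 frames")
    vs = series.voxel_size_mm
    mean = series.frames.mean(axis=3)
    vmax = series.frames.max(axis=3)
    vmin = series.frames.min(axis=3)
    return SummaryImages(
        Volume3D(mean, vs), Volume3D(vmax, vs), Volume3D(vmin, vs), Volume3D(vmax - vmin, vs)
    )


def vessel_mask_from_series(
    series: VolumeSeries,
    brain_mask: BinaryMask,
    thresholds: SegmentationThresholds | None = None,
) -> BinaryMask:
    """Flag vascular voxels inside the brain mask by enhancement thresholding."""
    require_same_grid(series.frames, brain_mask, "series and brain mask")
    if not brain_mask.values.any():
        raise InvalidParameterError("brain mask is empty")
    thr = thresholds or SegmentationThresholds()
    images = summary_images(series)
    diff = images.diff.values
    mean = images.mean.values

    diff_threshold = thr.diff_threshold
    if diff_threshold is None:
        in_brain = diff[brain_mask.values]
        positive = in_brain[in_brain > 0]
        if positive.size == 0:
            warnings.warn("no positive enhancement inside brain mask; empty vessel mask",
                          stacklevel=2)
            return BinaryMask(np.zeros(brain_mask.shape, dtype=bool), brain_mask.voxel_size_mm)
        diff_threshold = thr.enhancement_ratio * float(np.median(positive))

    vascular = diff > diff_threshold
    if thr.mean_threshold is not None:
        vascular |= mean > thr.mean_threshold
    return BinaryMask(vascular & brain_mask.values, brain_mask.voxel_size_mm)


def tissue_mask(brain_mask: BinaryMask, vessel_mask: BinaryMask) -> BinaryMask:
    """Tissue = brain minus vessels."""
    require_same_grid(brain_mask, vessel_mask, "brain and vessel masks")
    return BinaryMask(brain_mask.values & ~vessel_mask.values, brain_mask.voxel_size_mm)


def vessel_adjacent_roi(vessel_mask: BinaryMask, tissue: BinaryMask) -> BinaryMask:
    """Tissue voxels immediately adjacent to a vessel.

    One voxel-wise dilation of the vessel mask (full 3x3x3 structuring
    element, 26-connectivity) intersected with the tissue mask; the
    intersection eliminates the vascular voxels themselves.
    """
    require_same_grid(vessel_mask, tissue, "vessel and tissue masks")
    if not vessel_mask.values.any():
        warnings.warn("vessel mask is empty; ROI is empty", stacklevel=2)
        return BinaryMask(np.zeros(vessel_mask.shape, dtype=bool), vessel_mask.voxel_size_mm)
    dilated = ndimage.binary_dilation(
        vessel_mask.values, structure=np.ones((3, 3, 3), dtype=bool), iterations=1
    )
    return BinaryMask(dilated & tissue.values, vessel_mask.voxel_size_mm)


def brain_mask_fallback(
    series: VolumeSeries, hu_range: tuple[float, float] = (0.0, 100.0)
) -> BinaryMask:
    """Crude brain mask: HU band on the mean image, largest connected component.

    Convenience plumbing only -- real use should supply a skull-stripped
    brain mask; this stands in when none is available.
    """
    mean = summary_images(series).mean.values
    band = (mean > hu_range[0]) & (mean < hu_range[1])
    labelled, n = ndimage.label(band)
    if n == 0:
        return BinaryMask(band, series.voxel_size_mm)
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return BinaryMask(labelled == keep, series.voxel_size_mm)
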