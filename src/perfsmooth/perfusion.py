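"""CT-perfusion parametric maps: CBF (max slope), CBV (integral ratio), TTP.

Tissue and arterial enhancement curves are baseline-corrected time-activity
curves (TACs) in HU.  The maps are:

* ``CBF = 60 * max_t dC_tissue/dt / max(C_aif)``  [ml/(cc*min)] -- the
  classical maximum-slope estimate: the steepest tissue uptake normalized by
  the arterial peak.
* ``CBV = integral(C_tissue) / integral(C_aif)``  [ml/cc] -- trapezoidal
  integral ratio of tissue to arterial activity.
* ``TTP`` -- time of the maximum enhancement, in minutes (first occurrence
  on ties).  TTP is invariant under positive scaling of a curve, which is
  why Removed and Masked smoothing -- whose voxel curves differ only by the
  positive factor 1/SW when the mask is frame-independent -- give voxel-wise
  identical TTP maps.

The arterial input function (AIF) may be rescaled by integral matching
against a venous output function (VOF, e.g. sagittal sinus) to correct
partial-volume underestimation of the arterial curve.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BinaryMask, VolumeSeries, require_same_grid
from .errors import InvalidParameterError
from .kernels import KernelSpec
from .smoothing import Method, OutsidePolicy, smooth_series


@dataclass(frozen=True)
class TimeCurve:
    """A baseline-corrected enhancement curve in HU above baseline."""

    times_s: np.ndarray
    values: np.ndarray
    n_baseline: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise InvalidParameterError("times and values must be matching 1D vectors")
        if times.size == 0:
            raise InvalidParameterError("empty time curve")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not (1 <= self.n_baseline < max(times.size, 2)):
            raise InvalidParameterError(
                f"n_baseline must be in [1, n_frames), got {self.n_baseline}"
            )
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "values", values)

    def integral(self) -> float:
        """Trapezoidal time integral (HU*s)."""
        return float(np.trapezoid(self.values, self.times_s))


@dataclass(frozen=True)
class PerfusionMaps:
    """Voxel-wise CBF, CBV and TTP grids, defined (non-NaN) on the tissue mask."""

    cbf: np.ndarray  # ml/(cc*min)
    cbv: np.ndarray  # ml/cc
    ttp: np.ndarray  # minutes
    tissue_mask: BinaryMask


def extract_tac(series: VolumeSeries, roi: BinaryMask, n_baseline: int = 1) -> TimeCurve:
    """Per-frame ROI-mean curve, baseline-corrected.

    The baseline is the mean of the first ``n_baseline`` (pre-contrast)
    frames and is subtracted from the whole curve.
    """
    require_same_grid(series.frames, roi, "series and ROI")
    if not roi.values.any():
        raise InvalidParameterError("ROI is empty")
    raw = series.frames[roi.values].mean(axis=0)
    baseline = raw[:n_baseline].mean()
    return TimeCurve(series.frame_times_s, raw - baseline, n_baseline)


def scale_aif(aif: TimeCurve, vof: TimeCurve) -> TimeCurve:
    """Rescale the AIF so its integral matches the venous curve's integral."""
    aif_integral = aif.integral()
    if aif_integral <= 0:
        raise InvalidParameterError(f"AIF integral must be positive, got {aif_integral}")
    factor = vof.integral() / aif_integral
    return TimeCurve(aif.times_s, aif.values * factor, aif.n_baseline)


def cbf_max_slope(tissue: TimeCurve, aif: TimeCurve) -> float:
    """Maximum-slope CBF in ml/(cc*min); floors at zero."""
    if tissue.times_s.shape != aif.times_s.shape or not np.allclose(
        tissue.times_s, aif.times_s
    ):
        raise InvalidParameterError("tissue and AIF curves must share the time axis")
    peak = float(aif.values.max())
    if peak <= 0:
        raise InvalidParameterError(f"AIF peak must be positive, got {peak}")
    if tissue.values.size < 2:
        raise InvalidParameterError("need at least two frames for a slope")
    slopes = np.diff(tissue.values) / np.diff(tissue.times_s)
    return max(0.0, 60.0 * float(slopes.max()) / peak)


def cbv_ratio(tissue: TimeCurve, aif: TimeCurve) -> float:
    """Integral-ratio CBV in ml/cc."""
    aif_integral = aif.integral()
    if aif_integral <= 0:
        raise InvalidParameterError(f"AIF integral must be positive, got {aif_integral}")
    return tissue.integral() / aif_integral


def ttp(curve: TimeCurve) -> float:
    """Time of maximum enhancement, minutes; first occurrence on ties."""
    return float(curve.times_s[int(np.argmax(curve.values))]) / 60.0


def perfusion_maps(
    series: VolumeSeries,
    tissue_mask: BinaryMask,
    aif_roi: BinaryMask,
    vof_roi: BinaryMask | None = None,
    *,
    method: Method = "masked",
    spec: KernelSpec | None = None,
    vessel_mask: BinaryMask | None = None,
    n_baseline: int = 1,
    outside_policy: OutsidePolicy = "original",
) -> PerfusionMaps:
    """Smooth the series per ``method`` and compute voxel-wise CBF/CBV/TTP.

    The AIF (and VOF, when given) are extracted from the *unsmoothed* series:
    vessel ROI values are what the arterial curve is, regardless of how the
    tissue class is smoothed, and Removed smoothing would otherwise zero the
    very voxels the AIF is read from.  When a VOF ROI is supplied the AIF is
    integral-rescaled against the venous curve.
    """
    require_same_grid(series.frames, tissue_mask, "series and tissue mask")
    if method != "none":
        if spec is None:
            raise InvalidParameterError(f"method {method!r} requires a kernel spec")
        smoothed = smooth_series(
            series, method, spec,
            tissue_mask=tissue_mask, vessel_mask=vessel_mask,
            outside_policy=outside_policy,
        )
    else:
        smoothed = series

    aif = extract_tac(series, aif_roi, n_baseline)
    if vof_roi is not None:
        aif = scale_aif(aif, extract_tac(series, vof_roi, n_baseline))
    peak = float(aif.values.max())
    aif_integral = aif.integral()
    if peak <= 0 or aif_integral <= 0:
        raise InvalidParameterError("AIF must have positive peak and integral")

    times = smoothed.frame_times_s
    frames = smoothed.frames
    baseline = frames[..., :n_baseline].mean(axis=3, keepdims=True)
    enhancement = frames - baseline

    dt = np.diff(times)
    slopes = np.diff(enhancement, axis=3) / dt
    cbf = np.maximum(0.0, 60.0 * slopes.max(axis=3) / peak)
    cbv = np.trapezoid(enhancement, times, axis=3) / aif_integral
    ttp_map = times[np.argmax(enhancement, axis=3)] / 60.0

    outside = ~tissue_mask.values
    for grid in (cbf, cbv, ttp_map):
        grid[outside] = np.nan
    return PerfusionMaps(cbf, cbv, ttp_map, tissue_mask)
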