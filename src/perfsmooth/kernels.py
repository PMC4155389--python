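"""Separable, truncated, normalized discrete Gaussian kernels.

Kernels are specified physically, by Full Width at Half Maximum (FWHM) in mm
per spatial axis, and discretized on the voxel lattice of the target image.
A 3D Gaussian is separable -- the outer product of three 1D vectors -- so 3D
smoothing reduces to three successive 1D convolutions, which is what makes
mask-restricted Gaussian smoothing fast enough for clinical-sized volumes.

Discretization: the Gaussian is point-sampled at integer voxel offsets out to
a truncation radius ``r = round(truncation_sigmas * sigma / voxel_size)`` and
renormalized to unit sum, so the discrete kernel conserves total weight
exactly.  With the default truncation factor of 6 sigma this yields a
25x25x21-voxel kernel for a 2 mm FWHM on 0.42x0.42x0.5 mm voxels and an
in-plane length of 99 voxels at 8 mm FWHM.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Triple, as_triple
from .errors import InvalidParameterError

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian FWHM to its standard deviation (same units).

    Parameters
    ----------
    fwhm_mm : float
        Full width at half maximum, strictly positive.

    Returns
    -------
    float
        ``fwhm_mm / (2*sqrt(2*ln 2))`` (~ fwhm / 2.35482).
    """
    if not np.isfinite(fwhm_mm) or fwhm_mm <= 0:
        raise InvalidParameterError(f"FWHM must be positive and finite, got {fwhm_mm}")
    return fwhm_mm / FWHM_PER_SIGMA


@dataclass(frozen=True)
class KernelSpec:
    """Physical specification of a separable Gaussian kernel.

    ``fwhm_mm`` and ``voxel_size_mm`` may be given as scalars (isotropic) or
    per-axis triples; ``truncation_sigmas`` controls where the sampled
    Gaussian is cut off.
    """

    fwhm_mm: Triple
    voxel_size_mm: Triple
    truncation_sigmas: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwhm_mm", as_triple(self.fwhm_mm, "fwhm_mm"))
        object.__setattr__(self, "voxel_size_mm", as_triple(self.voxel_size_mm, "voxel_size_mm"))
        for name in ("fwhm_mm", "voxel_size_mm"):
            if any(v <= 0 or not np.isfinite(v) for v in getattr(self, name)):
                raise InvalidParameterError(f"{name} entries must be positive, got {getattr(self, name)}")
        if not np.isfinite(self.truncation_sigmas) or self.truncation_sigmas <= 0:
            raise InvalidParameterError(
                f"truncation_sigmas must be positive, got {self.truncation_sigmas}"
            )


@dataclass(frozen=True)
class SeparableKernel:
    """Three 1D weight vectors whose outer product is the 3D kernel.

    Each vector has odd length, is symmetric about its centre, unimodal with
    the maximum at the centre, and sums to one.
    """

    weights_x: np.ndarray
    weights_y: np.ndarray
    weights_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("weights_x", "weights_y", "weights_z"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.ndim != 1 or w.size % 2 != 1:
                raise InvalidParameterError(f"{name} must be a 1D vector of odd length")
            if np.any(w < 0):
                raise InvalidParameterError(f"{name} has negative weights")
            object.__setattr__(self, name, w)

    @property
    def axis_weights(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.weights_x, self.weights_y, self.weights_z

    @property
    def lengths(self) -> tuple[int, int, int]:
        return self.weights_x.size, self.weights_y.size, self.weights_z.size

    @property
    def radii(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.lengths)  # type: ignore[return-value]

    def center_weight(self) -> float:
        """Weight of the 3D outer-product kernel at its centre voxel."""
        return float(
            self.weights_x[self.weights_x.size // 2]
            * self.weights_y[self.weights_y.size // 2]
            * self.weights_z[self.weights_z.size // 2]
        )

    def outer(self) -> np.ndarray:
        """Materialize the full 3D kernel (for oracles and inspection)."""
        return np.einsum("i,j,k->ijk", self.weights_x, self.weights_y, self.weights_z)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of (axis, offset, weight) for CSV inspection."""
        rows = []
        for axis, w in zip("xyz", self.axis_weights):
            r = w.size // 2
            for k, wk in zip(range(-r, r + 1), w):
                rows.append({"axis": axis, "offset": k, "weight": wk})
        return pd.DataFrame(rows)


def gaussian_kernel_1d(
    fwhm_mm: float, voxel_size_mm: float, truncation_sigmas: float = 6.0
) -> np.ndarray:
    """Build a 1D truncated, renormalized Gaussian kernel on a voxel lattice.

    The truncation radius is ``round(truncation_sigmas * sigma / voxel)`` but
    at least 1, so the kernel always spans the immediate neighbours.
    """
    if not np.isfinite(voxel_size_mm) or voxel_size_mm <= 0:
        raise InvalidParameterError(f"voxel size must be positive, got {voxel_size_mm}")
    if not np.isfinite(truncation_sigmas) or truncation_sigmas <= 0:
        raise InvalidParameterError(f"truncation must be positive, got {truncation_sigmas}")
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = sigma_mm / voxel_size_mm
    radius = max(1, int(round(truncation_sigmas * sigma_vox)))
    offsets = np.arange(-radius, radius + 1, dtype=float)
    weights = np.exp(-(offsets**2) / (2.0 * sigma_vox**2))
    return weights / weights.sum()


def separable_kernel_3d(spec: KernelSpec) -> SeparableKernel:
    """Construct the per-axis kernels for a :class:`KernelSpec`.

    Anisotropic voxels are handled by building each axis kernel independently
    from the same physical FWHM, so kernel lengths differ per axis.
    """
    wx, wy, wz = (
        gaussian_kernel_1d(f, v, spec.truncation_sigmas)
        for f, v in zip(spec.fwhm_mm, spec.voxel_size_mm)
    )
    return SeparableKernel(wx, wy, wz)
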