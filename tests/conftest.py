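"""Shared fixtures and independent brute-force oracles.

The oracles compute smoothing by explicit window enumeration around each
voxel (zero padding realized by clipping windows at the grid edge), fully
independent of the separable-convolution path under test.
"""
from __future__ import annotations

import numpy as np
import pytest

from perfsmooth.containers import BinaryMask, Volume3D, VolumeSeries
from perfsmooth.kernels import SeparableKernel


def windowed_sums(
    values: np.ndarray,
    mask: np.ndarray | None,
    kernel: SeparableKernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (sum of w*v over mask, sum of w over mask) by direct windows.

    ``mask=None`` means all voxels count (plain zero-padded convolution:
    out-of-grid voxels contribute nothing to either sum).
    """
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    rx, ry, rz = kernel.radii
    wx, wy, wz = kernel.axis_weights
    nx, ny, nz = values.shape
    num = np.zeros(values.shape)
    den = np.zeros(values.shape)
    for i in range(nx):
        xs = slice(max(i - rx, 0), min(i + rx + 1, nx))
        kxs = slice(xs.start - (i - rx), (2 * rx + 1) - ((i + rx + 1) - xs.stop))
        for j in range(ny):
            ys = slice(max(j - ry, 0), min(j + ry + 1, ny))
            kys = slice(ys.start - (j - ry), (2 * ry + 1) - ((j + ry + 1) - ys.stop))
            for k in range(nz):
                zs = slice(max(k - rz, 0), min(k + rz + 1, nz))
                kzs = slice(zs.start - (k - rz), (2 * rz + 1) - ((k + rz + 1) - zs.stop))
                w = (
                    wx[kxs, None, None]
                    * wy[None, kys, None]
                    * wz[None, None, kzs]
                )
                m = mask[xs, ys, zs]
                num[i, j, k] = (w * values[xs, ys, zs] * m).sum()
                den[i, j, k] = (w * m).sum()
    return num, den


def convolve_oracle(values: np.ndarray, kernel: SeparableKernel) -> np.ndarray:
    """Zero-padded 3D convolution with the outer-product kernel, by windows."""
    num, _ = windowed_sums(values, None, kernel)
    return num


def masked_oracle(
    values: np.ndarray, mask: np.ndarray, kernel: SeparableKernel
) -> np.ndarray:
    """Renormalized-weight (within-mask weighted mean) smoothing, by windows.

    Returns NaN outside the mask.
    """
    num, den = windowed_sums(values, mask, kernel)
    out = np.full(values.shape, np.nan)
    out[mask] = num[mask] / den[mask]
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140821)


def random_volume(
    rng: np.random.Generator, shape=(9, 9, 9), voxel=(1.0, 1.0, 1.0)
) -> Volume3D:
    return Volume3D(rng.normal(50.0, 20.0, shape), voxel)


def random_mask(
    rng: np.random.Generator, shape=(9, 9, 9), p: float = 0.6, voxel=(1.0, 1.0, 1.0)
) -> BinaryMask:
    mask = rng.random(shape) < p
    if not mask.any():  # keep the mask non-empty for masked smoothing
        mask[tuple(s // 2 for s in shape)] = True
    return BinaryMask(mask, voxel)


def bolus_series(
    rng: np.random.Generator | None = None,
    shape=(10, 10, 6),
    n_frames: int = 12,
    dt: float = 3.0,
    noise_sd: float = 0.0,
) -> tuple[VolumeSeries, BinaryMask, BinaryMask]:
    """A synthetic contrast-passage series: vessel rod plus delayed tissue curves.

    Returns (series, tissue_mask, vessel_mask).  Vessel voxels follow a large
    early gamma-variate bolus; tissue voxels a smaller, delayed one whose
    delay varies with position (so TTP varies across the grid).
    """
    times = np.arange(n_frames) * dt
    vessel = np.zeros(shape, dtype=bool)
    cx = shape[0] // 2
    vessel[cx, shape[1] // 2 - 1 : shape[1] // 2 + 1, :] = True
    tissue = ~vessel

    def gamma_variate(t, t0, alpha, beta):
        shifted = np.maximum(t - t0, 0.0)
        return (shifted**alpha) * np.exp(-shifted / beta)

    frames = np.zeros(shape + (n_frames,))
    aif = gamma_variate(times, 3.0, 2.0, 3.0)
    aif = 400.0 * aif / aif.max()
    xs = np.arange(shape[0])
    for x in range(shape[0]):
        delay = 6.0 + 3.0 * (x % 3)
        curve = gamma_variate(times, delay, 2.0, 4.0)
        curve = 30.0 * curve / max(curve.max(), 1e-12)
        frames[x, :, :, :] = curve[None, None, :]
    frames[..., :] += 50.0
    frames[vessel, :] = 60.0 + aif[None, :]
    if noise_sd > 0 and rng is not None:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    voxel = (1.0, 1.0, 1.0)
    return (
        VolumeSeries(frames, voxel, times),
        BinaryMask(tissue, voxel),
        BinaryMask(vessel, voxel),
    )
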