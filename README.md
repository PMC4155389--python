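# perfsmooth

Masked (normalized-convolution) Gaussian smoothing and CBF/CBV/TTP parametric
maps for dynamic CT perfusion imaging.

## The problem

CT perfusion tissue voxels have poor SNR and are routinely smoothed, but
contrast-filled vessels can be several-fold brighter than the surrounding grey
and white matter. Ordinary Gaussian smoothing bleeds that vascular signal into
neighbouring tissue, inflating the tissue values and, downstream, the cerebral
blood flow (CBF) and cerebral blood volume (CBV) estimated from them. Zeroing
the vessels before smoothing just flips the bias downward.

**Masked smoothing** restricts the Gaussian average to one voxel class. With a
binary tissue mask `M` and image `I`, and a separable Gaussian kernel `G`:

```
masked(I) = G * (I · M)  /  G * M         (voxel-wise, on mask voxels)
```

The denominator `SW = G * M` is the *sum of weights* falling on same-class
voxels, so dividing by it rescales the in-class kernel weights to unit sum.
A within-class constant is reproduced exactly — the method is unbiased at
class boundaries — and because both convolutions use separable kernels (three
1D passes per volume) it stays fast even for large kernels. Voxels outside the
mask keep their original values (configurable: zero / NaN / smoothed as their
own class).

The package implements, on top of this core:

* **kernels** — truncated, renormalized discrete Gaussians from FWHM in mm and
  per-axis voxel sizes (radius `round(6σ/voxel)`; a 2 mm FWHM on
  0.42×0.42×0.5 mm voxels gives a 25×25×21-voxel kernel).
* **smoothing** — Simple / Removed / Masked / per-class multiclass smoothing of
  3D volumes and frame-wise 4D series.
* **segmentation** — vessel masks from the temporal mean and max−min images of
  a dynamic series; tissue = brain − vessel; the vessel-adjacent ROI
  (26-neighbour dilation ∩ tissue).
* **perfusion** — maximum-slope CBF, integral-ratio CBV and time-to-peak (TTP)
  maps from a smoothed series, with optional venous rescaling of the arterial
  input function.
* **simulation** — a vessel-in-tissue phantom study quantifying the bias and
  noise reduction of each smoothing method over repeated noise draws.

## Worked example

The phantom study at default conditions — a 100³ volume of 0.4 mm voxels,
tissue value 50, a 1.6 mm vessel rod at twice the tissue intensity, Gaussian
noise at SNR 2 (SD 25), 2 mm FWHM smoothing — tracks a tissue voxel directly
beside the vessel over 500 noise draws:

```python
from perfsmooth import SimulationConfig, run_simulation

summary = run_simulation(SimulationConfig(n_iterations=500, seed=42))
for method in ("none", "simple", "removed", "masked"):
    print(f"{method:>8}: mean {summary.mean[method]:6.2f}  sd {summary.sd[method]:5.2f}")
```

```
    none: mean  49.73  sd 24.75
  simple: mean  62.63  sd  1.18
 removed: mean  37.50  sd  1.00
  masked: mean  50.09  sd  1.33
```

The true tissue value is 50. Simple smoothing is biased up by the bright
vessel, Removed smoothing is biased down by the zeroed vessel voxels, and
Masked smoothing is unbiased — while all three cut the noise SD more than
ten-fold. The same comparison is available from the shell:

```bash
perfsmooth simulate --sweep intensity_ratio --iterations 500 --seed 42 -o results.csv
perfsmooth smooth scan.nii.gz --method masked --fwhm 4 --mask tissue.nii.gz -o out.nii.gz
perfsmooth perfusion series.nii.gz --tissue tissue.nii.gz --aif aif.nii.gz \
    --method masked --fwhm 4 --out-prefix maps
```

See `docs/methods.md` for the model details, parameter defaults and
limitations.

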