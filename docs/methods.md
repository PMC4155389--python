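# Methods

## Masked smoothing

Smoothing assigns each voxel a nonnegative-weighted average of its
neighbourhood. When the neighbourhood mixes classes (tissue next to a
contrast-filled vessel, or next to a zeroed background), the average is biased
toward the other class. Masked smoothing removes the cross-class terms by
renormalizing the weights to the voxel's own class: with binary class mask
`M`, image `I` and smoothing operator `S`,

```
masked(I)(v) = S(I·M)(v) / S(M)(v)     for v in the mask.
```

`S(M)` is the sum of weights (SW) landing on same-class voxels; on a voxel
whose whole neighbourhood is in-class, SW = 1 and the method reduces to plain
smoothing. Because the two passes use the same *separable* kernel, the cost is
six 1D convolutions per volume instead of one dense 3D convolution — the
property that makes the method practical at clinical volume sizes.

Key identities the test suite verifies:

* a within-class constant is reproduced exactly (unbiasedness mechanism);
* `masked ≡ simple` when the mask is all-true;
* the method is linear and monotone on the mask;
* at a tissue voxel beside a vessel of value `V > tissue`:
  `removed ≤ masked ≤ simple`.

Degenerate inputs: an empty mask is rejected; the SW denominator is guarded at
`1e-12` and raising on a mask voxel is treated as an internal error (a mask
voxel always carries at least its own centre weight, so the guard can only
trigger on NaN propagation). Non-finite input volumes are rejected up front.

## Kernels

Kernels are specified by FWHM in mm per axis (`σ = FWHM / (2√(2 ln 2))`) and
point-sampled at integer voxel offsets out to radius
`r = round(truncation_sigmas · σ / voxel_size)`, minimum 1, then renormalized
to unit sum. Point sampling plus renormalization (rather than erf-integration
over voxel extents) keeps the discrete kernel exactly mass-conserving, which
the masked quotient relies on. The default truncation factor of 6σ reproduces
the kernel sizes a clinical 0.42×0.42×0.5 mm grid requires: 25×25×21 voxels at
2 mm FWHM and 99 voxels in-plane at 8 mm. Anisotropic voxels get one 1D kernel
per axis from the same physical FWHM.

Boundary handling is zero padding for image and mask alike. For masked
smoothing the out-of-grid zeros cancel between numerator and denominator, so
mask voxels at the edge still receive the correct within-mask mean; for Simple
and Removed smoothing zero padding matches the zero border of the phantom
study and produces the expected edge underestimation.

## Segmentation

A dynamic series gives each voxel a fixed class, and contrast makes vessels
both bright on the temporal-mean image and strongly enhancing on the
max−min (`diff`) image. A voxel inside the brain mask is flagged vascular if
`diff` exceeds a threshold or (optionally) `mean` does. When no absolute HU
threshold is supplied, the diff threshold defaults to 4× the median positive
enhancement inside the brain — vessels enhance several-fold more than tissue —
and both absolute thresholds are exposed for protocols where calibrated values
are known. The vessel-adjacent tissue ROI is one dilation of the vessel mask
with the full 3×3×3 structuring element (26-connectivity, the most inclusive
choice; the connectivity is configurable nowhere because the ROI is only used
for reporting means) intersected with the tissue mask, which removes the
vessel voxels themselves. Skull stripping is out of scope: the brain mask is
an input, with `brain_mask_fallback` (HU band + largest connected component)
as explicitly crude plumbing.

## Perfusion maps

Curves are per-voxel (or ROI-mean) enhancements above baseline, the baseline
being the mean of the first `n_baseline` frames (default 1); negative
enhancements are not clipped. From tissue curve `C` and arterial input
function (AIF) `A` on a shared time axis:

* **CBF** `= 60 · max_t ΔC/Δt / max(A)` in ml/(cc·min) — the classical
  maximum-slope formulation with the arterial peak as denominator. Slopes are
  forward finite differences between consecutive frames (frame spacing is
  coarse, typically 3 s, so no spline is fitted); the maximum is taken over
  all slopes and the result floors at 0.
* **CBV** `= ∫C dt / ∫A dt` in ml/cc, trapezoidal integrals.
* **TTP** = time of maximum enhancement in minutes, first occurrence on ties.

The AIF and the optional venous curve (VOF) are extracted from the
*unsmoothed* series: vessel voxels are exactly what tissue-directed smoothing
should not alter (Removed smoothing zeroes them outright), and under Masked
smoothing they keep their original values anyway. When a VOF ROI is given the
AIF is rescaled by `∫VOF/∫AIF` to correct partial-volume underestimation of
the arterial curve; with no VOF the AIF is used as-is.

TTP is invariant under positive scaling of a curve. With a frame-independent
mask, the masked- and removed-smoothed curves of a tissue voxel differ only by
the constant positive factor 1/SW (when the non-tissue class is exactly the
vessel class), so their TTP maps agree voxel for voxel — the suite checks this
exactly. Absolute CBF/CBV levels depend on acquisition and AIF handling; only
orderings and invariances are asserted, and on synthetic series with dominant
vessel curves the maps order `CBV(removed) ≤ CBV(masked) ≤ CBV(simple)`.

## The simulation study

The phantom emulates the geometry that drives smoothing bias and nothing
else: a 100×100×100 grid of 0.4 mm isotropic voxels; uniform tissue at
value 50; a vessel rod along z spanning the non-border extent with a square
cross-section of `round(width/0.4)` voxels centred in x,y (the study varies
width over 0.8/1.6/2.4 mm → 2/4/6 voxels); and a 5-voxel zero border (2 mm —
thick enough that, for every tested FWHM, the border never reaches the probe).
The probe voxel sits face-adjacent to the rod in −x at the rod's axial
midpoint, centred on the rod in y. Each iteration adds i.i.d. Gaussian noise
of SD = 50/SNR to *every* voxel (SNR 1/2/3 → SD 50/25/50⁄3) and records the
probe under no smoothing, Simple, Removed and Masked smoothing; a run uses
500 iterations and reports the sample mean and SD per method. One parameter
is swept at a time over (intensity ratio 1.5/2/4, SNR 1/2/3, width
0.8/1.6/2.4 mm, FWHM 1/2/4 mm) with the others at defaults (2:1, SNR 2,
1.6 mm, 2 mm).

What the phantom does *not* emulate: partial-volume voxels at the
vessel–tissue interface, spatially correlated reconstruction noise, curved or
branching vessels, and contrast kinetics (intensities are static). Passing
the unbiasedness tests therefore shows the estimator property — masked
smoothing does not mix classes — not that segmentation of real data is easy;
a mis-segmented vessel voxel biases its neighbours upward (bounded by the
Simple-smoothing bias).

**Fast probe readout.** Every method's probe value is a linear functional of
the noise field restricted to the probe's kernel neighbourhood, so
`run_simulation` precomputes the deterministic part from the noise-free
phantom and per iteration evaluates three weighted sums over the local noise
patch. The full noise volume is still drawn from the seeded generator each
iteration, so the samples equal (to floating-point rounding) what whole-volume
smoothing produces — `run_iteration` implements that reference path and the
suite checks agreement on a reduced grid. This turns a multi-minute sweep into
seconds without changing the statistics. Reduced grids (24³–44³) are used in
unit tests purely to keep whole-volume reference convolutions cheap; all
study-condition results use the full 100³ grid.

Deterministic identities at zero noise, with `w` the kernel weight falling on
the vessel from the probe (border out of reach): `simple − 50 = w·(V − 50)`
and `50 − removed = w·50`, hence `(simple−50)/(50−removed) = (V−50)/50`
exactly — the suite verifies this to 1e-10 for ratios 1.5/2/4. The absolute
Simple/Removed means depend on `w`, i.e. on the exact rod cross-section and
probe offset (our square 4×4-voxel rod gives `w ≈ 0.25`); they are reported
but only the geometry-independent quantities (masked mean, SD fold-reduction,
noise calibration, bias identity) are asserted.

Seeds: a run is reproducible bit-for-bit from `SimulationConfig.seed`; sweeps
derive per-run seeds from the base seed via `numpy.random.SeedSequence`.

## Design choices where the design was open

* **Truncation rule** `r = round(6σ/voxel)`: chosen to match the clinical
  kernel sizes above; exposed as `truncation_sigmas`. On 0.5 mm slices at
  8 mm FWHM the rule gives 83 voxels.
* **Outside-mask policy**: `original` (default) / `zero` / `missing` (NaN);
  multiclass smoothing composes per-class masked smoothing instead.
* **Vessel geometry**: an axis-aligned square rod — the simplest "long thin"
  vessel; bias magnitudes depend on it, the masked mean does not.
* **Dilation connectivity** for the adjacency ROI: 26 (full 3×3×3), one
  iteration.
* **Frame times**: JSON sidecar (`{"frame_times_s": [...]}`) preferred,
  uniform-interval fallback (default 3 s).

## Limitations

* No deconvolution-based CBF/MTT, no HU→concentration conversion; CBF/CBV are
  relative unless the AIF is calibrated.
* No motion correction, DICOM ingestion or automatic artery selection; AIF and
  VOF ROIs are user inputs.
* Smoothing is purely spatial; the mask is shared across frames by design.
* Bilateral/adaptive filters are out of scope.
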