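"""Simple/Removed/Masked smoothing against brute-force window oracles."""
import numpy as np
import pytest

from perfsmooth import (
    BinaryMask,
    DataError,
    InvalidParameterError,
    KernelSpec,
    Volume3D,
    VolumeSeries,
    convolve_separable,
    masked_smooth,
    multiclass_smooth,
    removed_smooth,
    separable_kernel_3d,
    simple_smooth,
    smooth_series,
)
from conftest import convolve_oracle, masked_oracle, random_mask, random_volume

SPEC = KernelSpec(2.0, 1.0)  # 7-voxel kernels on a unit grid
KERNEL = separable_kernel_3d(SPEC)


class TestConvolveSeparable:
    def test_impulse_response_is_outer_product(self):
        rx, ry, rz = KERNEL.radii  # radius 5 for FWHM 2 mm on 1 mm voxels
        shape = (2 * rx + 3, 2 * ry + 3, 2 * rz + 3)
        c = tuple(s // 2 for s in shape)
        values = np.zeros(shape)
        values[c] = 1.0
        out = convolve_separable(Volume3D(values), KERNEL).values
        expected = np.zeros(shape)
        expected[
            c[0] - rx : c[0] + rx + 1, c[1] - ry : c[1] + ry + 1, c[2] - rz : c[2] + rz + 1
        ] = KERNEL.outer()
        assert np.allclose(out, expected, atol=1e-12)

    def test_constant_interior_unchanged(self):
        out = convolve_separable(Volume3D(np.full((15, 15, 15), 7.0)), KERNEL).values
        assert out[7, 7, 7] == pytest.approx(7.0, abs=1e-10)

    def test_matches_window_oracle(self, rng):
        volume = random_volume(rng)
        out = convolve_separable(volume, KERNEL).values
        assert np.allclose(out, convolve_oracle(volume.values, KERNEL), atol=1e-10)

    def test_nonfinite_rejected(self):
        values = np.zeros((5, 5, 5))
        values[0, 0, 0] = np.nan
        with pytest.raises(DataError):
            convolve_separable(Volume3D(values), KERNEL)

    def test_oversized_kernel_warns(self):
        with pytest.warns(UserWarning, match="kernel length"):
            convolve_separable(Volume3D(np.zeros((3, 3, 3))), KERNEL)


class TestSimpleSmooth:
    def test_constant_interior(self):
        result = simple_smooth(Volume3D(np.full((15, 15, 15), 50.0)), SPEC)
        assert result.smoothed.values[7, 7, 7] == pytest.approx(50.0, abs=1e-10)
        assert np.all(result.sw == 1.0)

    def test_high_neighbour_raises_probe(self, rng):
        values = np.full((9, 9, 9), 50.0)
        base = simple_smooth(Volume3D(values), SPEC).smoothed.values[4, 4, 4]
        values[5, 4, 4] = 500.0
        raised = simple_smooth(Volume3D(values), SPEC).smoothed.values[4, 4, 4]
        assert raised > base

    def test_matches_oracle(self, rng):
        volume = random_volume(rng)
        out = simple_smooth(volume, SPEC).smoothed.values
        assert np.allclose(out, convolve_oracle(volume.values, KERNEL), atol=1e-10)


class TestRemovedSmooth:
    def test_empty_vessel_equals_simple(self, rng):
        volume = random_volume(rng)
        empty = BinaryMask(np.zeros(volume.shape, dtype=bool))
        assert np.array_equal(
            removed_smooth(volume, empty, SPEC).smoothed.values,
            simple_smooth(volume, SPEC).smoothed.values,
        )

    def test_all_vessel_gives_zero(self, rng):
        volume = random_volume(rng)
        full = BinaryMask(np.ones(volume.shape, dtype=bool))
        assert np.allclose(removed_smooth(volume, full, SPEC).smoothed.values, 0.0)

    def test_definitional_identity(self, rng):
        volume = random_volume(rng)
        vessel = random_mask(rng, p=0.3)
        zeroed = Volume3D(np.where(vessel.values, 0.0, volume.values))
        assert np.allclose(
            removed_smooth(volume, vessel, SPEC).smoothed.values,
            simple_smooth(zeroed, SPEC).smoothed.values,
            atol=1e-12,
        )

    def test_shape_mismatch(self, rng):
        with pytest.raises(DataError):
            removed_smooth(
                random_volume(rng), BinaryMask(np.zeros((4, 4, 4), dtype=bool)), SPEC
            )


class TestMaskedSmooth:
    def test_all_true_mask_reduces_to_simple(self, rng):
        volume = random_volume(rng, shape=(13, 13, 13))
        mask = BinaryMask(np.ones(volume.shape, dtype=bool))
        masked = masked_smooth(volume, mask, SPEC).smoothed.values
        simple = simple_smooth(volume, SPEC).smoothed.values
        # interior equals simple; at edges the zero padding cancels between
        # numerator and denominator so the quotient is the within-grid mean,
        # which the window oracle reproduces
        interior = tuple(slice(5, -5) for _ in range(3))
        assert np.allclose(masked[interior], simple[interior], atol=1e-12)
        assert np.allclose(masked, masked_oracle(volume.values, mask.values, KERNEL),
                           atol=1e-10)

    def test_within_mask_constant_preserved(self, rng):
        mask = random_mask(rng, p=0.4)
        values = rng.normal(500.0, 100.0, mask.shape)
        values[mask.values] = 50.0
        out = masked_smooth(Volume3D(values), mask, SPEC).smoothed.values
        assert np.allclose(out[mask.values], 50.0, atol=1e-10)

    def test_matches_renormalized_weight_oracle(self, rng):
        volume = random_volume(rng)
        mask = random_mask(rng)
        out = masked_smooth(volume, mask, SPEC).smoothed.values
        expected = masked_oracle(volume.values, mask.values, KERNEL)
        assert np.allclose(out[mask.values], expected[mask.values], rtol=1e-10, atol=1e-10)

    @pytest.mark.parametrize("policy, check", [
        ("original", lambda out, vol, m: np.array_equal(out[~m], vol[~m])),
        ("zero", lambda out, vol, m: np.all(out[~m] == 0.0)),
        ("missing", lambda out, vol, m: np.all(np.isnan(out[~m]))),
    ])
    def test_outside_policies(self, rng, policy, check):
        volume = random_volume(rng)
        mask = random_mask(rng, p=0.5)
        out = masked_smooth(volume, mask, SPEC, outside_policy=policy).smoothed.values
        assert check(out, volume.values, mask.values)
        assert not np.any(np.isnan(out[mask.values]))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            masked_smooth(
                random_volume(rng),
                BinaryMask(np.zeros((9, 9, 9), dtype=bool)),
                SPEC,
            )

    def test_sw_is_convolved_mask(self, rng):
        volume = random_volume(rng)
        mask = random_mask(rng)
        result = masked_smooth(volume, mask, SPEC)
        expected_sw = convolve_separable(
            Volume3D(mask.values.astype(float)), KERNEL
        ).values
        assert np.allclose(result.sw, expected_sw, atol=1e-12)

    def test_sw_bounds(self, rng):
        mask = random_mask(rng)
        result = masked_smooth(random_volume(rng), mask, SPEC)
        assert np.all(result.sw <= 1 + 1e-10)
        # every mask voxel carries at least its own centre weight
        assert np.all(result.sw[mask.values] >= KERNEL.center_weight() - 1e-12)

    def test_linearity_on_mask(self, rng):
        volume = random_volume(rng)
        mask = random_mask(rng)
        a, b = 2.5, -7.0
        scaled = Volume3D(a * volume.values + b)
        out_scaled = masked_smooth(scaled, mask, SPEC).smoothed.values
        out = masked_smooth(volume, mask, SPEC).smoothed.values
        assert np.allclose(
            out_scaled[mask.values], a * out[mask.values] + b, rtol=1e-9, atol=1e-9
        )

    def test_monotonicity(self, rng):
        volume = random_volume(rng)
        mask = random_mask(rng)
        out = masked_smooth(volume, mask, SPEC).smoothed.values
        bumped = volume.values.copy()
        target = tuple(np.argwhere(mask.values)[0])
        bumped[target] += 100.0
        out_bumped = masked_smooth(Volume3D(bumped), mask, SPEC).smoothed.values
        assert np.all(out_bumped[mask.values] >= out[mask.values] - 1e-10)


def test_method_ordering_next_to_bright_vessel():
    """At a tissue voxel beside a bright vessel: removed <= masked <= simple."""
    shape = (15, 15, 15)
    values = np.full(shape, 50.0)
    vessel = np.zeros(shape, dtype=bool)
    vessel[8:10, :, :] = True
    values[vessel] = 400.0
    tissue = BinaryMask(~vessel)
    volume = Volume3D(values)
    probe = (7, 7, 7)
    simple = simple_smooth(volume, SPEC).smoothed.values[probe]
    removed = removed_smooth(volume, BinaryMask(vessel), SPEC).smoothed.values[probe]
    masked = masked_smooth(volume, tissue, SPEC).smoothed.values[probe]
    assert removed <= masked <= simple
    assert masked == pytest.approx(50.0, abs=1e-9)


class TestMulticlassSmooth:
    def test_piecewise_constant_identity(self, rng):
        labels = (rng.random((9, 9, 9)) < 0.5).astype(int)
        values = np.where(labels == 1, 80.0, 20.0)
        out = multiclass_smooth(Volume3D(values), labels, SPEC).values
        assert np.allclose(out, values, atol=1e-10)

    def test_single_class_equals_simple_interior(self, rng):
        volume = random_volume(rng, shape=(13, 13, 13))
        out = multiclass_smooth(volume, np.zeros(volume.shape, dtype=int), SPEC).values
        simple = simple_smooth(volume, SPEC).smoothed.values
        interior = tuple(slice(5, -5) for _ in range(3))
        assert np.allclose(out[interior], simple[interior], atol=1e-10)

    def test_each_class_matches_its_own_oracle(self, rng):
        volume = random_volume(rng)
        labels = rng.integers(0, 3, volume.shape)
        out = multiclass_smooth(volume, labels, SPEC).values
        for label in range(3):
            mask = labels == label
            expected = masked_oracle(volume.values, mask, KERNEL)
            assert np.allclose(out[mask], expected[mask], rtol=1e-10, atol=1e-10)


class TestSmoothSeries:
    def test_masked_linearity_across_frames(self, rng):
        frame = rng.normal(50, 10, (9, 9, 9))
        frames = np.stack([frame, 3 * frame], axis=-1)
        series = VolumeSeries(frames, (1, 1, 1), [0.0, 3.0])
        mask = random_mask(rng)
        out = smooth_series(series, "masked", SPEC, tissue_mask=mask)
        m = mask.values
        assert np.allclose(out.frames[m, 1], 3 * out.frames[m, 0], rtol=1e-9)

    def test_single_frame_equals_3d_operation(self, rng):
        volume = random_volume(rng)
        series = VolumeSeries(volume.values[..., None], (1, 1, 1), [0.0])
        out = smooth_series(series, "simple", SPEC)
        assert np.allclose(
            out.frames[..., 0], simple_smooth(volume, SPEC).smoothed.values
        )

    @pytest.mark.parametrize("method", ["simple", "removed", "masked"])
    def test_framewise_equivalence(self, rng, method):
        frames = rng.normal(50, 10, (8, 8, 8, 4))
        series = VolumeSeries(frames, (1, 1, 1), np.arange(4) * 3.0)
        mask = random_mask(rng, shape=(8, 8, 8))
        vessel = BinaryMask(~mask.values)
        out = smooth_series(series, method, SPEC, tissue_mask=mask, vessel_mask=vessel)
        for t in range(4):
            frame = series.frame(t)
            if method == "simple":
                expected = simple_smooth(frame, SPEC).smoothed.values
            elif method == "removed":
                expected = removed_smooth(frame, vessel, SPEC).smoothed.values
            else:
                expected = masked_smooth(frame, mask, SPEC).smoothed.values
            assert np.allclose(out.frames[..., t], expected, atol=1e-12)

    def test_missing_mask_rejected(self, rng):
        series = VolumeSeries(rng.normal(size=(5, 5, 5, 2)), (1, 1, 1), [0.0, 3.0])
        with pytest.raises(InvalidParameterError):
            smooth_series(series, "masked", SPEC)
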