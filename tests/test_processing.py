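"""Tests of gain correction, summation, binning, scaling, sharpening,
and the pixel-statistics diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from edframes import (
    EventField,
    EventList,
    GainMap,
    bin_frame,
    compression_ratio,
    default_kernel_bank,
    frame_stats,
    gain_correct,
    log_histogram,
    render_events_with_kernels,
    scale_for_integer_output,
    sharpen,
    simulate_counts,
    sum_batches,
)
from conftest import event_count_image, isolated_events


class TestGainCorrect:
    def test_unit_gain_is_identity(self, rng):
        frame = rng.poisson(3.0, (16, 16))
        out = gain_correct(frame, np.ones((16, 16)))
        assert np.array_equal(out, frame)

    def test_unnormalized_uniform_gain_scales(self):
        out = gain_correct(np.ones((4, 4)), np.full((4, 4), 2.0),
                           normalize=False)
        assert np.all(out == 2.0)

    def test_normalized_gain_preserves_mean(self, rng):
        gain = rng.uniform(0.5, 1.5, (64, 64))
        out = gain_correct(np.full((64, 64), 7.0), gain)
        assert out.mean() == pytest.approx(7.0, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            gain_correct(np.ones((4, 4)), np.ones((5, 5)))

    def test_nonpositive_gain_names_pixel(self):
        gain = np.ones((3, 3))
        gain[1, 2] = 0.0
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            gain_correct(np.ones((3, 3)), gain)

    def test_normalized_flag_validated(self):
        with pytest.raises(ValueError):
            GainMap(np.full((4, 4), 2.0), normalized=True)


class TestSumBatches:
    def test_group_of_one_is_identity(self, rng):
        stack = rng.integers(0, 5, (4, 8, 8))
        out, dropped = sum_batches(stack, 1)
        assert dropped == 0 and np.array_equal(out, stack)

    def test_binary_frames_capped_by_group(self, rng):
        stack = rng.integers(0, 2, (10, 8, 8))
        out, _ = sum_batches(stack, 10)
        assert out.shape[0] == 1 and out.max() <= 10

    def test_incomplete_trailing_group_dropped(self, rng):
        stack = rng.integers(0, 3, (7, 4, 4))
        with pytest.warns(UserWarning, match="dropping 1"):
            out, dropped = sum_batches(stack, 3)
        assert out.shape[0] == 2 and dropped == 1
        assert out.sum() == stack[:6].sum()

    def test_counts_conserved_exactly(self, rng):
        stack = rng.integers(0, 100, (12, 16, 16))
        out, _ = sum_batches(stack, 4)
        assert out.sum() == stack.sum()
        assert np.issubdtype(out.dtype, np.integer)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sum_batches(np.empty((0, 4, 4)), 2)


class TestBinFrame:
    def test_factor_one_identity(self, rng):
        frame = rng.integers(0, 9, (6, 6))
        assert np.array_equal(bin_frame(frame, 1), frame)

    def test_two_by_two_pooling(self):
        out = bin_frame(np.ones((4, 4), dtype=int), 2)
        assert np.array_equal(out, np.full((2, 2), 4))

    def test_counts_conserved(self, rng):
        frame = rng.integers(0, 50, (12, 18))
        assert bin_frame(frame, 3).sum() == frame.sum()

    def test_non_divisible_advises_crop(self):
        with pytest.raises(ValueError, match="crop"):
            bin_frame(np.ones((5, 4)), 2)


class TestScaleForIntegerOutput:
    def test_unit_value_scales_to_32(self):
        out, clamped = scale_for_integer_output(np.array([[1.0]]))
        assert out[0, 0] == 32 and clamped == 0

    def test_zero_stays_zero(self):
        out, _ = scale_for_integer_output(np.zeros((2, 2)))
        assert not out.any()

    def test_overflow_clamped_and_reported(self):
        out, clamped = scale_for_integer_output(np.array([[3000.0, 1.0]]))
        assert out[0, 0] == 65535 and out[0, 1] == 32 and clamped == 1

    def test_half_to_even_rounding(self):
        out, _ = scale_for_integer_output(
            np.array([[0.5, 1.5]]), scale=1.0
        )
        assert list(out[0]) == [0, 2]

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            scale_for_integer_output(np.ones((2, 2)), scale=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(hnp.arrays(np.float64, (12,),
                      elements=st.floats(-10, 3000)))
    def test_monotone(self, values):
        frame = np.sort(values).reshape(1, -1)
        out, _ = scale_for_integer_output(frame)
        assert np.all(np.diff(out[0].astype(int)) >= 0)


class TestSharpen:
    def test_zero_frame(self):
        events, residual, mask = sharpen(np.zeros((16, 16)))
        assert not events.any() and not residual.any() and not mask.any()

    def test_single_event_exact_inverse(self):
        ev = EventList(x=[7], y=[9], dx=[0.8], dy=[0.3], frame=[0])
        frame = render_events_with_kernels(ev, (16, 16))
        events, residual, mask = sharpen(frame)
        assert events[9, 7] == 1 and events.sum() == 1
        assert abs(residual).sum() < 1e-6
        assert not mask.any()

    def test_isolated_events_round_trip_exact(self, rng):
        ev = isolated_events(rng, 200, (512, 512), min_separation=5)
        frame = render_events_with_kernels(ev, (512, 512))
        events, residual, _ = sharpen(frame, min_separation=5)
        assert np.array_equal(events, event_count_image(ev, (512, 512)))
        assert abs(residual).sum() < 1e-6

    def test_round_trip_many_seeds(self):
        # flagship property: exact recovery across independent layouts
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ev = isolated_events(rng, 40, (128, 128), min_separation=5)
            frame = render_events_with_kernels(ev, (128, 128))
            events, residual, _ = sharpen(frame, min_separation=5)
            assert np.array_equal(events,
                                  event_count_image(ev, (128, 128))), seed
            assert abs(residual).sum() < 1e-6

    def test_dense_pair_masked_and_untouched(self):
        ev = EventList(x=[20, 21], y=[20, 20], dx=[0.3, 0.3],
                       dy=[0.3, 0.3], frame=[0, 0])
        frame = render_events_with_kernels(ev, (40, 40))
        events, residual, mask = sharpen(frame, min_separation=3)
        assert mask.any()
        # residual equals the original frame where events were revoked
        assert np.allclose(residual[mask], frame[mask])

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sharpen(np.full((8, 8), -1.0))


class TestDiagnostics:
    def test_histogram_zero_frame(self):
        hist = log_histogram(np.zeros((8, 8)))
        center_bin = np.searchsorted(hist.bin_edges, 0.0) - 1
        assert hist.interior_counts[center_bin] == 64
        assert hist.counts.sum() == 64

    def test_counting_frame_is_integer_concentrated(self):
        frame, _, events = simulate_counts(
            EventField(np.full((128, 128), 0.5)), 10, seed=3
        )
        st_ = frame_stats(frame.data)
        assert st_.integerness_fraction > 0.99
        rendered = render_events_with_kernels(events, (128, 128))
        st_r = frame_stats(rendered)
        assert st_r.integerness_fraction < st_.integerness_fraction - 0.05

    def test_histogram_requires_two_edges(self):
        with pytest.raises(ValueError):
            log_histogram(np.zeros((4, 4)), bin_edges=[0.0])

    def test_histogram_overflow_bins(self):
        hist = log_histogram(np.array([[-5.0, 0.0, 99.0]]),
                             bin_edges=[-0.25, 0.25])
        assert hist.counts[0] == 1 and hist.counts[-1] == 1
        assert hist.counts.sum() == 3

    def test_stats_zero_frame(self):
        st_ = frame_stats(np.zeros((8, 8)))
        assert st_.zero_fraction == 1.0 and st_.max_value == 0.0

    def test_stats_saturated_frame(self):
        st_ = frame_stats(np.full((8, 8), 10), cap=10)
        assert st_.saturated_fraction == 1.0

    def test_low_flux_frame_mostly_zero(self):
        frame, _, _ = simulate_counts(
            EventField(np.full((256, 256), 0.005)), 10, seed=4
        )
        assert frame_stats(frame.data).zero_fraction > 0.9

    def test_compression_constant_frame(self):
        assert compression_ratio(np.zeros((256, 256), dtype=np.uint16)) > 50

    def test_compression_random_noise_incompressible(self, rng):
        noise = rng.integers(0, 65536, (256, 256)).astype(np.uint16)
        assert compression_ratio(noise) < 1.1

    def test_compression_sparse_counting_frame(self):
        frame, _, _ = simulate_counts(
            EventField(np.full((256, 256), 0.01)), 10, seed=5
        )
        data = frame.data.astype(np.uint16)
        assert frame_stats(data).zero_fraction > 0.9
        assert compression_ratio(data) > 5

    def test_compression_requires_integers(self):
        with pytest.raises(TypeError):
            compression_ratio(np.zeros((4, 4)))
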