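"""Trace processing, spike detection, and quality metrics.

Brute-force reimplementations (direct sums, direct DFT) serve as
independent oracles for the vectorized metric implementations.
"""

import numpy as np
import pytest

from voltdenoise.analysis import (
    ProcessedTrace,
    compute_fwhm,
    detect_spikes,
    extract_traces,
    pcc,
    preprocess_trace,
    reference_trace,
    spatial_metrics,
    spike_segments,
    split_by_snr,
    temporal_snr,
)
from voltdenoise.video import ROISet, VideoStack

RATE = 803.0


def make_processed(values, rate=RATE):
    return ProcessedTrace(values=np.asarray(values, dtype=float), frame_rate=rate)


class TestExtractTraces:
    def test_single_pixel_roi_returns_pixel_series(self, rng):
        data = rng.random((20, 8, 8))
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 4] = 1
        traces = extract_traces(VideoStack(data), ROISet(labels))
        assert np.array_equal(traces[1], data[:, 3, 4])

    def test_mean_of_two_constant_pixels(self):
        data = np.zeros((5, 4, 4))
        data[:, 0, 0] = 2.0
        data[:, 0, 1] = 4.0
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = labels[0, 1] = 7
        traces = extract_traces(VideoStack(data), ROISet(labels))
        assert list(traces) == [7]
        assert np.allclose(traces[7], 3.0)

    def test_roi_ids_preserved(self, small_bundle):
        traces = extract_traces(small_bundle.noisy, small_bundle.rois)
        assert sorted(traces) == small_bundle.rois.roi_ids


class TestPreprocessTrace:
    def test_output_mean_absolute_value_is_one(self, rng):
        raw = rng.random(4000) + np.linspace(0, 3, 4000)
        out = preprocess_trace(raw, RATE)
        assert np.abs(out.values).mean() == pytest.approx(1.0)

    def test_constant_trace_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess_trace(np.full(3000, 2.0), RATE)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            preprocess_trace(np.ones(100), RATE)

    def test_narrow_pulse_survives_baseline_subtraction(self):
        # boxcar attenuation: a w-sample pulse loses w/W of its height to a
        # centred W-sample moving average
        n = 5000
        w = 8
        window = int(round(2.5 * RATE))
        raw = np.linspace(0, 5, n)  # slow drift
        raw[2500 : 2500 + w] += 1.0
        out = preprocess_trace(raw, RATE)
        # undo the normalization to compare amplitudes in raw units
        scale = np.abs(
            raw
            - np.convolve(np.pad(raw, window // 2, mode="reflect"),
                          np.ones(window) / window, mode="same")[window // 2 : window // 2 + n]
        ).mean()
        peak = out.values.max() * scale
        assert peak == pytest.approx(1.0, abs=0.05)
        assert 1.0 - peak <= 0.05  # < 5% amplitude loss


class TestComputeFwhm:
    def test_triangular_peak(self):
        # rises over 4 samples, falls over 4: half-max sits 2 samples out
        vals = np.concatenate([np.zeros(5), np.linspace(0, 1, 5), np.linspace(1, 0, 5)[1:], np.zeros(5)])
        peak = int(np.argmax(vals))
        assert compute_fwhm(vals, peak, RATE) == pytest.approx(4.0 / RATE)

    def test_gaussian_peak_closed_form(self):
        sigma = 3.0
        x = np.arange(-30, 31)
        vals = np.exp(-(x**2) / (2 * sigma**2))
        fwhm = compute_fwhm(vals, 30, RATE)
        assert fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma / RATE, rel=0.02)

    def test_single_sample_impulse(self):
        vals = np.zeros(11)
        vals[5] = 6.0
        assert compute_fwhm(vals, 5, RATE) == pytest.approx(1.0 / RATE)

    def test_unbounded_flank_returns_nan(self):
        vals = np.concatenate([np.linspace(1, 2, 10), [2.5], np.full(5, 2.4)])
        assert np.isnan(compute_fwhm(vals, 10, RATE)) or compute_fwhm(vals, 10, RATE) > 0


class TestDetectSpikes:
    def _trace_with_peak(self, amp, t_peak=0.55, n=2500, width=4):
        vals = np.zeros(n)
        i = int(round(t_peak * RATE))
        ramp = np.linspace(0, 1, width + 1)
        vals[i - width : i + 1] = amp * ramp
        vals[i : i + width + 1] = amp * ramp[::-1]
        return make_processed(vals)

    def test_amplitude_above_threshold_in_window_detected(self):
        trace = self._trace_with_peak(6.0)
        events = detect_spikes(trace, stimulus_onsets=[0.5])
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(0.55, abs=0.01)
        assert events[0].fwhm > 0

    def test_amplitude_below_threshold_ignored(self):
        events = detect_spikes(self._trace_with_peak(3.0), stimulus_onsets=[0.5])
        assert events == []

    def test_peak_outside_stimulus_window_ignored(self):
        events = detect_spikes(self._trace_with_peak(6.0, t_peak=0.8), [0.5])
        assert events == []

    def test_min_distance_keeps_larger_peak(self):
        n = 2500
        vals = np.zeros(n)
        i1, i2 = int(0.52 * RATE), int(0.57 * RATE)  # 0.05 s apart
        for i, amp in ((i1, 6.0), (i2, 5.0)):
            vals[i - 2 : i + 1] = np.linspace(0, amp, 3)
            vals[i : i + 3] = np.linspace(amp, 0, 3)
        events = detect_spikes(make_processed(vals), [0.5])
        assert len(events) == 1
        assert events[0].peak_amplitude == pytest.approx(6.0)

    def test_empty_onsets_give_empty_result(self):
        assert detect_spikes(self._trace_with_peak(6.0), []) == []


class TestTemporalSnr:
    def test_hand_computed_example(self):
        vals = np.zeros(100)
        vals[10:20] = 2.0
        seg = np.zeros(100, dtype=bool)
        seg[10:20] = True
        trace = make_processed(vals)
        # signal power 4, noise power 0.4 -> SNR 10
        assert temporal_snr(trace, segments=seg) == pytest.approx(10.0)

    def test_segments_covering_whole_trace_give_unity(self, rng):
        trace = make_processed(rng.standard_normal(500))
        assert temporal_snr(trace, segments=np.ones(500, bool)) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        vals = rng.standard_normal(500)
        vals[100:110] += 5
        seg = np.zeros(500, bool)
        seg[100:110] = True
        a = temporal_snr(make_processed(vals), segments=seg)
        b = temporal_snr(make_processed(7.5 * vals), segments=seg)
        assert a == pytest.approx(b)

    def test_strictly_increases_with_signal_amplitude(self, rng):
        noise = rng.standard_normal(500)
        seg = np.zeros(500, bool)
        seg[100:110] = True
        snrs = []
        for amp in (2.0, 5.0, 10.0):
            vals = noise.copy()
            vals[100:110] += amp
            snrs.append(temporal_snr(make_processed(vals), segments=seg))
        assert snrs[0] < snrs[1] < snrs[2]

    def test_no_spikes_reports_zero_with_warning(self, rng):
        trace = make_processed(rng.standard_normal(100))
        with pytest.warns(UserWarning):
            assert temporal_snr(trace, spikes=[]) == 0.0

    def test_zero_power_raises(self):
        with pytest.raises(ValueError):
            temporal_snr(make_processed(np.zeros(100)), segments=np.ones(100, bool))

    def test_matches_brute_force_on_random_trace(self, rng):
        vals = rng.standard_normal(800)
        seg = rng.random(800) < 0.1
        if not seg.any():
            seg[0] = True
        got = temporal_snr(make_processed(vals), segments=seg)
        sig = sum(v**2 for v, s in zip(vals, seg) if s) / seg.sum()
        noi = sum(v**2 for v in vals) / len(vals)
        assert got == pytest.approx(sig / noi, rel=1e-9)


class TestSpatialMetrics:
    def test_frequency_axis_respects_anisotropic_nyquist(self, rng):
        frame = rng.random((32, 32))
        sm = spatial_metrics(frame, pixel_size_x=1.0, pixel_size_y=2.1)
        # radial bins stop at the lower of the two Nyquist limits:
        # 0.5 cyc/um along x, ~0.238 cyc/um along y
        assert sm.freqs.max() <= min(0.5, 0.5 / 2.1) + 1e-9
        assert sm.cutoff_freq <= 0.5 / 2.1

    def test_white_noise_cuts_off_at_lowest_frequencies(self, rng):
        frame = rng.standard_normal((64, 64))
        sm = spatial_metrics(frame, 1.0, 1.0)
        assert sm.cutoff_freq <= sm.freqs[4]  # flat PSD: floor met immediately
        assert sm.spatial_snr < 1.0

    def test_cutoff_increases_as_noise_decreases(self, rng):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2)) / (2 * 2.0**2))
        cutoffs = []
        for noise_sd in (0.5, 0.1, 0.005):
            frame = blob + noise_sd * np.random.default_rng(5).standard_normal((64, 64))
            cutoffs.append(spatial_metrics(frame, 1.0, 1.0).cutoff_freq)
        assert cutoffs[0] <= cutoffs[1] <= cutoffs[2]
        assert cutoffs[2] > cutoffs[0]

    def test_cutoff_invariant_under_intensity_scaling(self, rng):
        frame = rng.random((32, 32)) + 5
        a = spatial_metrics(frame, 1.0, 2.1)
        b = spatial_metrics(100.0 * frame, 1.0, 2.1)
        assert a.cutoff_freq == pytest.approx(b.cutoff_freq)
        assert a.resolution == pytest.approx(1.0 / a.cutoff_freq)

    def test_flat_frame_raises(self):
        with pytest.raises(ValueError, match="no spectral content"):
            spatial_metrics(np.full((32, 32), 3.0))

    def test_small_frame_raises(self, rng):
        with pytest.raises(ValueError):
            spatial_metrics(rng.random((8, 8)))

    def test_psd_matches_direct_dft_oracle(self, rng):
        frame = rng.random((16, 16))
        sm = spatial_metrics(frame, 1.0, 1.0)
        # direct DFT periodogram, O(N^4)
        H = W = 16
        x = frame - frame.mean()
        direct = np.zeros((H, W))
        for ky in range(H):
            for kx in range(W):
                phase = np.exp(
                    -2j * np.pi * (ky * np.arange(H)[:, None] / H + kx * np.arange(W)[None, :] / W)
                )
                direct[ky, kx] = np.abs((x * phase).sum()) ** 2 / (H * W)
        fy = np.fft.fftfreq(H, 1.0)
        fx = np.fft.fftfreq(W, 1.0)
        fr = np.hypot(fy[:, None], fx[None, :])
        df = 1.0 / 16
        edges = np.arange(df / 2, 0.5 + df, df)
        for i, c in enumerate(sm.freqs):
            sel = (fr >= edges[i]) & (fr < edges[i + 1])
            assert sm.psd[i] == pytest.approx(direct[sel].mean(), rel=1e-9)


class TestPcc:
    def test_self_correlation_is_one(self, rng):
        x = rng.random(50)
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_alternating_sequences_anticorrelate(self):
        a = np.tile([1.0, 0.0], 10)
        b = np.tile([0.0, 1.0], 10)
        assert pcc(a, b) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.arange(1000)
        assert pcc(np.sin(2 * np.pi * t / 100), np.cos(2 * np.pi * t / 100)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_explicit_formula(self, rng):
        a, b = rng.random(64), rng.random(64)
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert pcc(a, b) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pcc(np.ones(10), np.arange(10.0))

    def test_reference_trace_is_seven_frame_moving_average(self):
        x = np.zeros(21)
        x[10] = 7.0
        ref = reference_trace(x)
        assert ref[10] == pytest.approx(1.0)
        assert ref[7] == pytest.approx(1.0)
        assert ref[6] == pytest.approx(0.0)


class TestSplitBySnr:
    def test_even_count(self):
        low, high = split_by_snr({1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0})
        assert (low, high) == ([1, 2], [3, 4])

    def test_odd_count_median_joins_low(self):
        low, high = split_by_snr({1: 1.0, 2: 2.0, 3: 3.0})
        assert (low, high) == ([1, 2], [3])

    def test_ties_broken_stably_by_id(self):
        low, high = split_by_snr({4: 1.0, 2: 1.0, 3: 1.0, 1: 1.0})
        assert (low, high) == ([1, 2], [3, 4])

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            split_by_snr({1: 2.0})


class TestSpikeSegments:
    def test_segment_spans_one_fwhm(self):
        from voltdenoise.analysis import SpikeEvent

        e = SpikeEvent(peak_time=0.5, peak_amplitude=6.0, fwhm=0.01, peak_index=int(0.5 * RATE))
        seg = spike_segments([e], n_samples=1000, frame_rate=1000.0)
        assert seg[495:506].all()
        assert not seg[:490].any() and not seg[515:].any()
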