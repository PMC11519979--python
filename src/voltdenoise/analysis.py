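"""Trace extraction, spike detection and performance metrics.

Temporal pipeline: ROI traces (mean over ROI pixels per frame) are detrended
with a centred 2.5-s moving average, normalized by the mean absolute value
of the detrended trace, and evoked potentials are detected as peaks above a
threshold of 4 within 0-0.1 s after each stimulus onset, at least 0.1 s
apart; each spike is annotated with its full width at half maximum (FWHM)
and spikes with outlying FWHM (outside mean +- 3 SD) are discarded.

Temporal SNR is the mean power inside spike-width segments divided by the
mean power of the whole trace (a noise estimate valid for sparse signals).
Spatial quality comes from the radially averaged power spectral density of
single frames: the cutoff frequency where the PSD first meets the noise
floor gives the effective resolution (its reciprocal), and the spatial SNR
is the power below the cutoff over the power above it. Reference-based
Pearson correlations (PCC) use the temporal-average frame spatially and a
seven-frame moving average of the raw trace temporally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .video import ROISet, VideoStack

__all__ = [
    "ProcessedTrace",
    "SpikeEvent",
    "SpatialMetrics",
    "TemporalMetrics",
    "extract_traces",
    "preprocess_trace",
    "detect_spikes",
    "compute_fwhm",
    "temporal_snr",
    "spike_segments",
    "spatial_metrics",
    "pcc",
    "reference_frame",
    "reference_trace",
    "split_by_snr",
]

DETECTION_THRESHOLD = 4.0
DETECTION_WINDOW_S = 0.1
MIN_DISTANCE_S = 0.1
BASELINE_WINDOW_S = 2.5


@dataclass
class ProcessedTrace:
    """Baseline-subtracted, amplitude-normalized ROI time trace."""

    values: np.ndarray
    frame_rate: float
    baseline_window_s: float = BASELINE_WINDOW_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


@dataclass
class SpikeEvent:
    peak_time: float  # s
    peak_amplitude: float  # normalized units
    fwhm: float  # s
    peak_index: int


@dataclass
class SpatialMetrics:
    freqs: np.ndarray  # cycles/um, radial bin centres
    psd: np.ndarray
    noise_floor: float
    cutoff_freq: float  # cycles/um
    resolution: float  # um (= 1 / cutoff)
    spatial_snr: float


@dataclass
class TemporalMetrics:
    temporal_snr: float
    n_spikes: int
    mean_fwhm: float  # s, nan if no spikes
    temporal_pcc: float = np.nan
    spatial_pcc: float = np.nan


def extract_traces(video: VideoStack, rois: ROISet) -> dict[int, np.ndarray]:
    """Per-ROI raw traces: mean over the ROI's pixels in each frame."""
    out: dict[int, np.ndarray] = {}
    for roi_id in rois.roi_ids:
        mask = rois.mask(roi_id)
        out[roi_id] = video.data[:, mask].mean(axis=1)
    return out


def preprocess_trace(
    raw: np.ndarray, frame_rate: float, baseline_window_s: float = BASELINE_WINDOW_S
) -> ProcessedTrace:
    """Detrend with a centred moving average, then amplitude-normalize.

    The residual is divided by its own mean absolute value, so a threshold
    of 4 means "four times the typical excursion" regardless of gain or
    drift level. Raises on a constant (degenerate) trace.
    """
    raw = np.asarray(raw, dtype=np.float64)
    window = int(round(baseline_window_s * frame_rate))
    if len(raw) < window:
        raise ValueError(
            f"trace of {len(raw)} frames is shorter than the "
            f"{window}-frame baseline window"
        )
    baseline = uniform_filter1d(raw, size=window, mode="reflect")
    residual = raw - baseline
    scale = np.abs(residual).mean()
    if scale == 0:
        raise ValueError("degenerate trace: no variation after baseline subtraction")
    return ProcessedTrace(values=residual / scale, frame_rate=frame_rate,
                          baseline_window_s=baseline_window_s)


def compute_fwhm(values: np.ndarray, peak_index: int, frame_rate: float) -> float:
    """Full width at half maximum of a local peak, in seconds.

    Half-maximum crossing times on each flank are located by linear
    interpolation between samples. Returns nan if a flank never falls below
    half maximum (the caller discards such events).
    """
    values = np.asarray(values, dtype=np.float64)
    peak = values[peak_index]
    half = peak / 2.0

    def _cross(direction: int) -> Optional[float]:
        i = peak_index
        while 0 <= i + direction < len(values):
            j = i + direction
            if values[j] <= half:
                # interpolate between i (above) and j (at/below)
                frac = (values[i] - half) / (values[i] - values[j])
                return abs(i - peak_index) + frac
            i = j
        return None

    left = _cross(-1)
    right = _cross(+1)
    if left is None or right is None:
        return float("nan")
    return (left + right) / frame_rate


def detect_spikes(
    trace: ProcessedTrace,
    stimulus_onsets: Sequence[float],
    threshold: float = DETECTION_THRESHOLD,
    min_distance_s: float = MIN_DISTANCE_S,
    window_s: float = DETECTION_WINDOW_S,
    fwhm_sd_limit: float = 3.0,
) -> list[SpikeEvent]:
    """Stimulus-locked peak detection with FWHM-based outlier rejection.

    Peaks above ``threshold`` within [onset, onset + window_s] of any
    stimulus onset are kept; among peaks closer than ``min_distance_s`` the
    larger wins. Each retained peak is annotated with its FWHM, and events
    whose FWHM falls outside mean +- ``fwhm_sd_limit`` SD of the detected
    population (or whose FWHM is undefined) are discarded.
    """
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        return []
    values = trace.values
    rate = trace.frame_rate
    distance = max(1, int(round(min_distance_s * rate)))
    peaks, _ = find_peaks(values, height=threshold, distance=distance)
    if peaks.size == 0:
        return []
    times = peaks / rate
    in_window = np.zeros(len(peaks), dtype=bool)
    for onset in onsets:
        in_window |= (times >= onset) & (times <= onset + window_s)
    peaks = peaks[in_window]

    events = []
    for p in peaks:
        fwhm = compute_fwhm(values, int(p), rate)
        if not np.isfinite(fwhm):
            warnings.warn(
                f"spike at {p / rate:.4f}s discarded: trace never falls below "
                "half maximum on one side",
                stacklevel=2,
            )
            continue
        events.append(SpikeEvent(peak_time=p / rate, peak_amplitude=float(values[p]),
                                 fwhm=fwhm, peak_index=int(p)))
    if len(events) >= 2:
        fwhms = np.array([e.fwhm for e in events])
        mu, sd = fwhms.mean(), fwhms.std()
        if sd > 0:
            events = [e for e in events if abs(e.fwhm - mu) <= fwhm_sd_limit * sd]
    return events


def spike_segments(
    spikes: Sequence[SpikeEvent], n_samples: int, frame_rate: float
) -> np.ndarray:
    """Boolean mask of samples lying within the width of any spike.

    A spike's segment spans one FWHM centred on its peak.
    """
    mask = np.zeros(n_samples, dtype=bool)
    for e in spikes:
        half = e.fwhm / 2.0
        lo = max(0, int(np.floor((e.peak_time - half) * frame_rate)))
        hi = min(n_samples, int(np.ceil((e.peak_time + half) * frame_rate)) + 1)
        mask[lo:hi] = True
    return mask


def temporal_snr(
    trace: ProcessedTrace,
    spikes: Optional[Sequence[SpikeEvent]] = None,
    segments: Optional[np.ndarray] = None,
) -> float:
    """Signal power within spike segments over the power of the whole trace.

    Because the signals are sparse, the mean power of the entire trace is a
    serviceable noise estimate. Segments may be given directly as a boolean
    mask (e.g. from ground-truth spike times); otherwise they are derived
    from the detected spikes' widths. Returns 0 (with a warning) when there
    are no segments.
    """
    values = trace.values
    total_power = float(np.mean(values**2))
    if total_power == 0:
        raise ValueError("zero total power: empty or constant trace")
    if segments is None:
        if not spikes:
            warnings.warn("no spikes: temporal SNR reported as 0", stacklevel=2)
            return 0.0
        segments = spike_segments(spikes, len(values), trace.frame_rate)
    segments = np.asarray(segments, dtype=bool)
    if not segments.any():
        warnings.warn("empty signal segments: temporal SNR reported as 0", stacklevel=2)
        return 0.0
    signal_power = float(np.mean(values[segments] ** 2))
    return signal_power / total_power


def spatial_metrics(
    frame: np.ndarray,
    pixel_size_x: float = 1.0,
    pixel_size_y: float = 2.1,
    noise_floor_fraction: float = 0.1,
) -> SpatialMetrics:
    """PSD-based resolution and spatial SNR of a single frame.

    The 2-D periodogram of the mean-subtracted frame is radially averaged in
    physical frequency units (cycles/um), honouring anisotropic pixels. The
    noise floor is the mean PSD over the top ``noise_floor_fraction`` of
    frequencies; the cutoff is the lowest frequency where the PSD does not
    exceed the floor, the resolution its reciprocal, and the spatial SNR the
    total power below the cutoff over the total power above it.
    """
    frame = np.asarray(frame, dtype=np.float64)
    H, W = frame.shape
    if H < 16 or W < 16:
        raise ValueError("frame must be at least 16x16 for a meaningful PSD")
    centred = frame - frame.mean()
    if not centred.any():
        raise ValueError("no spectral content: frame is flat")
    spec = np.abs(np.fft.fft2(centred)) ** 2 / (H * W)
    fy = np.fft.fftfreq(H, d=pixel_size_y)
    fx = np.fft.fftfreq(W, d=pixel_size_x)
    fr = np.hypot(fy[:, None], fx[None, :])

    # radial bins in physical units; width set by the fundamental frequency
    # of the coarser-sampled axis, range limited to the lower Nyquist
    coarse_d = max(pixel_size_x, pixel_size_y)
    n_coarse = H if pixel_size_y >= pixel_size_x else W
    df = 1.0 / (n_coarse * coarse_d)
    f_max = min(0.5 / pixel_size_x, 0.5 / pixel_size_y)
    edges = np.arange(df / 2, f_max + df, df)
    centres = (edges[:-1] + edges[1:]) / 2.0
    psd = np.empty(len(centres))
    for i in range(len(centres)):
        sel = (fr >= edges[i]) & (fr < edges[i + 1])
        psd[i] = spec[sel].mean() if sel.any() else np.nan
    valid = np.isfinite(psd)
    centres, psd = centres[valid], psd[valid]

    n_floor = max(1, int(round(noise_floor_fraction * len(psd))))
    noise_floor = float(psd[-n_floor:].mean())
    below = np.flatnonzero(psd <= noise_floor)
    cutoff = float(centres[below[0]]) if below.size else float(centres[-1])

    signal_band = centres < cutoff
    p_sig = float(psd[signal_band].sum())
    p_noise = float(psd[~signal_band].sum())
    snr = p_sig / p_noise if p_noise > 0 else np.inf
    return SpatialMetrics(freqs=centres, psd=psd, noise_floor=noise_floor,
                          cutoff_freq=cutoff, resolution=1.0 / cutoff, spatial_snr=snr)


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length arrays."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def reference_frame(video: VideoStack) -> np.ndarray:
    """Spatial reference: the temporal average frame."""
    return video.data.mean(axis=0)


def reference_trace(raw_trace: np.ndarray, window: int = 7) -> np.ndarray:
    """Temporal reference: a seven-frame moving average of the raw trace."""
    return uniform_filter1d(np.asarray(raw_trace, dtype=np.float64), size=window,
                            mode="reflect")


def split_by_snr(fov_snrs: dict[int, float]) -> tuple[list[int], list[int]]:
    """Split fields of view into low/high halves by mean temporal SNR.

    Sorted ascending (stable in FOV id on ties); with an odd count the
    median FOV joins the low-SNR subset.
    """
    if len(fov_snrs) < 2:
        raise ValueError("need at least 2 FOVs to split")
    order = sorted(fov_snrs, key=lambda k: (fov_snrs[k], k))
    n_high = len(order) // 2
    low = order[: len(order) - n_high]
    high = order[len(order) - n_high :]
    return low, high
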