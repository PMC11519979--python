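"""Synthetic low-photon voltage-imaging videos with known ground truth.

The generator emulates the statistical structure that self-supervised
denoising assumes in kilohertz-rate voltage imaging: membrane-shaped
(annular) neurons on a dim background, stimulus-locked millisecond-scale
spikes riding on the membrane fluorescence, and Poisson-dominated shot
noise whose per-pixel variance is proportional to its mean. Default
intensities put essentially all raw pixel values below 10 counts — the
extreme low-photon regime the denoiser is designed for.

Ground truth (clean expected counts, ROI masks, spike times) is retained so
that downstream metrics can be validated against a known answer, which real
in vivo recordings never provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .video import (
    DEFAULT_FRAME_RATE,
    DEFAULT_PIXEL_SIZE_X,
    DEFAULT_PIXEL_SIZE_Y,
    ROISet,
    VideoStack,
)

__all__ = [
    "ScenePhantom",
    "ActivityModel",
    "GroundTruthBundle",
    "SimConfig",
    "generate_scene",
    "make_activity",
    "render_clean_video",
    "apply_photon_noise",
    "generate_dataset",
    "spike_kernel",
]

MIN_DIM = 16  # smallest frame that can hold one annular neuron


@dataclass
class ScenePhantom:
    """Static scene: annular membrane masks on a smooth background.

    ``background_map`` holds the baseline brightness (expected counts per
    frame) of every pixel, membrane pixels included; ``membrane_masks`` mark
    which pixels belong to which neuron.
    """

    height: int
    width: int
    membrane_masks: list[np.ndarray]
    background_map: np.ndarray
    pixel_size_x: float = DEFAULT_PIXEL_SIZE_X
    pixel_size_y: float = DEFAULT_PIXEL_SIZE_Y

    def __post_init__(self) -> None:
        if self.background_map.shape != (self.height, self.width):
            raise ValueError("background_map shape mismatch")
        if (self.background_map < 0).any():
            raise ValueError("background_map must be non-negative")
        for k, m in enumerate(self.membrane_masks):
            if m.shape != (self.height, self.width):
                raise ValueError(f"mask {k} shape mismatch")
            if not m.any():
                raise ValueError(f"membrane mask {k} is empty")

    @property
    def neuron_count(self) -> int:
        return len(self.membrane_masks)

    def roi_set(self) -> ROISet:
        """Label map with neuron k labelled k+1 (later neurons overwrite)."""
        labels = np.zeros((self.height, self.width), dtype=np.int32)
        for k, m in enumerate(self.membrane_masks):
            labels[m] = k + 1
        return ROISet(labels, roi_ids=list(range(1, self.neuron_count + 1)))


@dataclass
class ActivityModel:
    """Temporal activity: stimulus onsets and per-neuron spikes.

    Spikes are positive-going dF/F transients (time in seconds, amplitude as
    a fraction of baseline fluorescence) convolved with an asymmetric
    double-exponential kernel of configurable full width at half maximum.
    ``subthreshold_sd`` adds smooth low-amplitude membrane-potential
    fluctuations (dF/F units); it defaults to zero so that frames without an
    active spike equal the static scene exactly.
    """

    frame_rate: float = DEFAULT_FRAME_RATE
    stimulus_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    spikes: list[list[tuple[float, float]]] = field(default_factory=list)
    spike_fwhm_ms: float = 10.0
    subthreshold_sd: float = 0.0
    subthreshold_seed: int = 0

    def __post_init__(self) -> None:
        self.stimulus_onsets = np.asarray(self.stimulus_onsets, dtype=float)
        for k, sp in enumerate(self.spikes):
            for t, a in sp:
                if a <= 0:
                    raise ValueError(
                        f"neuron {k}: spike amplitudes must be positive (got {a})"
                    )

    @property
    def neuron_count(self) -> int:
        return len(self.spikes)


@dataclass
class GroundTruthBundle:
    """A simulated recording with its ground truth."""

    clean: VideoStack
    noisy: VideoStack
    rois: ROISet
    spike_times: dict[int, np.ndarray]  # roi_id -> seconds
    stimulus_onsets: np.ndarray
    gain: float

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy stacks must share shape")


@dataclass
class SimConfig:
    """Default study conditions for one synthetic field of view.

    Intensity defaults (background ~0.5 counts, membrane ~4 counts at unit
    gain) reproduce the low-photon regime where nearly all raw pixel
    readouts are below 10. Stimuli arrive as 5-puff 10-Hz trains repeated
    every 4 s; each neuron responds to most puffs with a millisecond-scale
    evoked potential shortly after onset.
    """

    height: int = 64
    width: int = 64
    neuron_count: int = 4
    duration_s: float = 5.0
    frame_rate: float = DEFAULT_FRAME_RATE
    background_level: float = 0.5
    membrane_level: float = 4.0
    gain: float = 1.0
    spike_amplitude: float = 0.4  # dF/F at the kernel peak
    spike_fwhm_ms: float = 10.0
    response_probability: float = 0.9
    train_start_s: float = 0.3
    train_interval_s: float = 4.0
    puffs_per_train: int = 5
    puff_rate_hz: float = 10.0
    subthreshold_sd: float = 0.08


def generate_scene(
    height: int, width: int, neuron_count: int, rng_seed: int
) -> ScenePhantom:
    """Place ``neuron_count`` annular membranes on a smooth dim background.

    Deterministic given the seed. Raises if the frame is too small to hold
    one annulus.
    """
    if height < MIN_DIM or width < MIN_DIM:
        raise ValueError(
            f"frame must be at least {MIN_DIM}x{MIN_DIM} pixels to fit an "
            f"annular neuron; got {height}x{width}"
        )
    if neuron_count < 0:
        raise ValueError("neuron_count must be >= 0")
    rng = np.random.default_rng(rng_seed)

    yy, xx = np.mgrid[0:height, 0:width]
    # gentle illumination gradient so the background is not perfectly flat
    grad = 0.15 * (xx / max(width - 1, 1)) + 0.1 * (yy / max(height - 1, 1))
    background = np.ones((height, width)) * (1.0 + grad - 0.125)

    max_r = min(height, width) // 2 - 2
    masks: list[np.ndarray] = []
    for _ in range(neuron_count):
        r_out = float(rng.uniform(4.0, min(7.0, max_r)))
        thickness = float(rng.uniform(1.2, 2.2))
        cy = float(rng.uniform(r_out + 1, height - r_out - 1))
        cx = float(rng.uniform(r_out + 1, width - r_out - 1))
        d = np.hypot(yy - cy, xx - cx)
        mask = (d <= r_out) & (d >= r_out - thickness)
        masks.append(mask)
    return ScenePhantom(height, width, masks, background)


def spike_kernel(
    fwhm_ms: float, frame_rate: float, rise_fraction: float = 0.25
) -> np.ndarray:
    """Asymmetric double-exponential evoked-potential waveform, peak 1.

    ``k(t) = exp(-t/tau_d) - exp(-t/tau_r)`` with a fast rise and slower
    decay; the time axis is rescaled so the sampled waveform attains the
    requested full width at half maximum. Returned sampled at ``frame_rate``
    and truncated where it falls below 1e-3 of the peak.
    """
    if fwhm_ms <= 0:
        raise ValueError("fwhm_ms must be positive")
    tau_r, tau_d = rise_fraction, 1.0  # shape units; rescaled below
    # measure the shape's FWHM on a dense grid
    tt = np.linspace(0, 12.0, 24001)
    shape = np.exp(-tt / tau_d) - np.exp(-tt / tau_r)
    shape /= shape.max()
    above = np.flatnonzero(shape >= 0.5)
    shape_fwhm = tt[above[-1]] - tt[above[0]]
    scale = (fwhm_ms / 1000.0) / shape_fwhm  # seconds per shape unit

    dt = 1.0 / frame_rate
    n = max(int(np.ceil(12.0 * scale / dt)), 3)
    t = np.arange(n) * dt / scale
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k = np.maximum(k, 0.0)
    k /= k.max()
    keep = np.flatnonzero(k >= 1e-3)
    return k[: keep[-1] + 1]


def make_activity(config: SimConfig, rng_seed: int) -> ActivityModel:
    """Stimulus trains plus per-neuron evoked spikes.

    Each neuron responds to each puff with probability
    ``response_probability``, at a latency uniform in 10-60 ms after onset
    (inside the 0-0.1 s detection window) and an amplitude jittered +-20%
    around ``spike_amplitude``.
    """
    rng = np.random.default_rng(rng_seed)
    onsets = []
    t = config.train_start_s
    while t < config.duration_s - 0.12:
        for i in range(config.puffs_per_train):
            o = t + i / config.puff_rate_hz
            if o < config.duration_s - 0.12:
                onsets.append(o)
        t += config.train_interval_s
    onsets_arr = np.array(onsets)

    spikes: list[list[tuple[float, float]]] = []
    for _ in range(config.neuron_count):
        events = []
        for o in onsets_arr:
            if rng.random() < config.response_probability:
                latency = rng.uniform(0.01, 0.06)
                amp = config.spike_amplitude * rng.uniform(0.8, 1.2)
                events.append((float(o + latency), float(amp)))
        spikes.append(events)
    return ActivityModel(
        frame_rate=config.frame_rate,
        stimulus_onsets=onsets_arr,
        spikes=spikes,
        spike_fwhm_ms=config.spike_fwhm_ms,
        subthreshold_sd=config.subthreshold_sd,
        subthreshold_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _activity_traces(activity: ActivityModel, n_frames: int) -> np.ndarray:
    """Per-neuron dF/F traces of length n_frames (kernel-convolved spikes)."""
    rate = activity.frame_rate
    kernel = spike_kernel(activity.spike_fwhm_ms, rate)
    traces = np.zeros((activity.neuron_count, n_frames))
    for k, events in enumerate(activity.spikes):
        for t_s, amp in events:
            i0 = int(round(t_s * rate))
            if i0 >= n_frames:
                raise ValueError(
                    f"spike at {t_s:.4f}s falls outside the video duration "
                    f"({n_frames / rate:.4f}s)"
                )
            seg = kernel[: n_frames - i0]
            traces[k, i0 : i0 + len(seg)] += amp * seg
    if activity.subthreshold_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        srng = np.random.default_rng(activity.subthreshold_seed)
        raw = srng.standard_normal((activity.neuron_count, n_frames))
        smooth = gaussian_filter1d(raw, sigma=rate * 0.01, axis=1, mode="reflect")
        sd = smooth.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        traces += activity.subthreshold_sd * smooth / sd
    return traces


def render_clean_video(
    scene: ScenePhantom,
    activity: ActivityModel,
    duration_s: float,
    membrane_level: float = 4.0,
) -> VideoStack:
    """Noise-free expected photon counts.

    Fluorescence model: membrane pixels of neuron k emit
    ``membrane_level * background_map * (1 + a_k(t))`` where ``a_k`` is the
    neuron's dF/F trace; everything else stays at the baseline
    ``background_map``.
    """
    if activity.neuron_count != scene.neuron_count:
        raise ValueError("activity and scene disagree on neuron count")
    n_frames = int(round(duration_s * activity.frame_rate))
    traces = _activity_traces(activity, n_frames)

    base = scene.background_map.copy()
    for m in scene.membrane_masks:
        base[m] = membrane_level * scene.background_map[m]

    clean = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    for k, m in enumerate(scene.membrane_masks):
        clean[:, m] = base[m][None, :] * (1.0 + traces[k][:, None])
    clean = np.maximum(clean, 0.0)
    return VideoStack(
        clean,
        frame_rate=activity.frame_rate,
        pixel_size_x=scene.pixel_size_x,
        pixel_size_y=scene.pixel_size_y,
    )


def apply_photon_noise(clean: VideoStack, gain: float, rng_seed: int) -> VideoStack:
    """Poisson shot noise with detector gain.

    Each pixel reads ``gain * Poisson(clean)``, so the per-pixel temporal
    variance-to-mean ratio equals ``gain`` (the photon-transfer relation
    that the beta estimator and the degradation simulator rely on).
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if (clean.data < 0).any():
        raise ValueError("clean video must be non-negative")
    rng = np.random.default_rng(rng_seed)
    counts = gain * rng.poisson(clean.data).astype(np.float64)
    return clean.with_data(counts)


def generate_dataset(config: SimConfig, rng_seed: int) -> GroundTruthBundle:
    """Compose scene, activity, rendering and shot noise into one bundle.

    The single seed fans out into independent per-component streams, so the
    whole bundle is a pure function of (config, seed).
    """
    ss = np.random.SeedSequence(rng_seed)
    s_scene, s_act, s_noise = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    scene = generate_scene(config.height, config.width, config.neuron_count, s_scene)
    scene.background_map *= config.background_level
    activity = make_activity(config, s_act)
    clean = render_clean_video(
        scene, activity, config.duration_s, membrane_level=config.membrane_level / config.background_level
    )
    noisy = apply_photon_noise(clean, config.gain, s_noise)
    rois = scene.roi_set()
    spike_times = {
        k + 1: np.array([t for t, _ in activity.spikes[k]])
        for k in range(config.neuron_count)
    }
    return GroundTruthBundle(
        clean=clean,
        noisy=noisy,
        rois=rois,
        spike_times=spike_times,
        stimulus_onsets=activity.stimulus_onsets,
        gain=config.gain,
    )
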