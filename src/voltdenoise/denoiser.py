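"""Self-supervised frame-by-frame denoising with blind-pixel masking.

The main branch takes N = 2*N0 + 1 consecutive frames (the central one
"degraded" by replacing a random fraction p_blind of its pixels with values
drawn from the same frame) plus the side-branch spatial-prior channels, and
is trained to reproduce the original noisy central frame with a mean
squared error evaluated *only at the blind pixels*. Because the network
never sees the true value of a blind pixel, it cannot learn the identity
map; it must infer each pixel from its spatiotemporal context, which is
exactly the denoising operation. At inference no pixels are masked and
every frame is denoised from its own assembled input.

The default training schedule: Adam, 360 steps per epoch with
batches of four samples, stopping after three passes over the dataset, an
initial learning rate of 5e-6 halved whenever the validation loss plateaus
over the last 288,000 samples, floored at 1e-7. Desk-scale runs override
these via :class:`TrainConfig`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .nn import Adam, DenoiserNet
from .prior import PriorStack, local_mean_frame, edge_channels, reflect_indices
from .video import VideoStack

__all__ = [
    "ModelSpec",
    "BlindMask",
    "TrainConfig",
    "TrainingHistory",
    "TrainedModel",
    "sample_blind_mask",
    "apply_blind_pixels",
    "assemble_input",
    "masked_mse",
    "masked_mse_grad",
    "train",
    "denoise_video",
]


@dataclass
class ModelSpec:
    """Network and window configuration.

    ``n_frames`` (N) controls temporal smoothing, ``m_frames`` (M) the
    spatial-prior quality; the two are independent, which is what decouples
    temporal from spatial performance. Defaults are the recommended
    operating point:
    N=7, M=all, p_blind=0.5%.
    """

    n_frames: int = 7
    m_frames: Union[int, str] = "all"
    variant: str = "E"
    p_blind: float = 0.005
    n_res_blocks: int = 4
    feature_width: int = 64
    kernel_size: int = 3
    blur_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_frames < 3 or self.n_frames % 2 == 0:
            raise ValueError(f"n_frames must be odd and >= 3; got {self.n_frames}")
        if isinstance(self.m_frames, str):
            if self.m_frames != "all":
                raise ValueError("m_frames must be an odd int or 'all'")
        elif self.m_frames < 1 or self.m_frames % 2 == 0:
            raise ValueError(f"m_frames must be odd and >= 1; got {self.m_frames}")
        if self.variant not in ("E", "M"):
            raise ValueError(f"variant must be 'E' or 'M'; got {self.variant!r}")
        if not 0 <= self.p_blind < 1:
            raise ValueError(f"p_blind must be in [0, 1); got {self.p_blind}")

    @property
    def prior_channels(self) -> int:
        return 4 if self.variant == "E" else 1

    @property
    def input_channels(self) -> int:
        return self.n_frames + self.prior_channels

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "m_frames": self.m_frames,
            "variant": self.variant,
            "p_blind": self.p_blind,
            "n_res_blocks": self.n_res_blocks,
            "feature_width": self.feature_width,
            "kernel_size": self.kernel_size,
            "blur_sigma": self.blur_sigma,
        }


@dataclass
class BlindMask:
    """The set of masked pixel coordinates of one frame."""

    coordinates: np.ndarray  # (n, 2) int array of (row, col)
    p_blind: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.intp).reshape(-1, 2)

    def __len__(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class TrainConfig:
    """Optimization schedule; defaults are sized for large training corpora."""

    steps_per_epoch: int = 360
    batch_size: int = 4
    dataset_passes: int = 3
    lr_init: float = 5e-6
    lr_min: float = 1e-7
    plateau_window_samples: int = 288_000
    plateau_improve_tol: float = 1e-3  # "fails to improve by > 0.1%"
    patch_size: int = 64
    val_fraction: float = 0.05
    seed: int = 0
    max_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must be <= lr_init")
        for name in ("steps_per_epoch", "batch_size", "dataset_passes",
                     "plateau_window_samples", "patch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    samples_seen: list[int] = field(default_factory=list)
    val_windows: list[tuple[int, float]] = field(default_factory=list)
    lr_events: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reuse it."""

    net: DenoiserNet
    spec: ModelSpec
    norm_mean: float
    norm_sd: float

    def save(self, path) -> None:
        manifest = json.dumps(
            {"spec": self.spec.to_dict(), "norm_mean": self.norm_mean, "norm_sd": self.norm_sd}
        )
        state = {f"param::{k}": v for k, v in self.net.state_dict().items()}
        np.savez(path, manifest=np.frombuffer(manifest.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as archive:
            manifest = json.loads(bytes(archive["manifest"]).decode())
            state = {k[len("param::"):]: archive[k] for k in archive.files if k.startswith("param::")}
        spec = ModelSpec(**manifest["spec"])
        if isinstance(spec.m_frames, np.integer):
            spec.m_frames = int(spec.m_frames)
        net = DenoiserNet(
            spec.input_channels, spec.feature_width, spec.n_res_blocks, spec.kernel_size
        )
        net.load_state_dict(state)
        return cls(net=net, spec=spec, norm_mean=float(manifest["norm_mean"]),
                   norm_sd=float(manifest["norm_sd"]))


def sample_blind_mask(
    frame_shape: tuple[int, int], p_blind: float, rng: np.random.Generator
) -> BlindMask:
    """Draw round(p_blind * H * W) distinct uniformly random coordinates."""
    if not 0 <= p_blind < 1:
        raise ValueError(f"p_blind must be in [0, 1); got {p_blind}")
    H, W = frame_shape
    n = int(round(p_blind * H * W))
    flat = rng.choice(H * W, size=n, replace=False)
    coords = np.stack([flat // W, flat % W], axis=1)
    return BlindMask(coordinates=coords, p_blind=p_blind)


def apply_blind_pixels(
    frame: np.ndarray, mask: BlindMask, rng: np.random.Generator
) -> np.ndarray:
    """Replace each blind pixel by a uniformly chosen pixel of the frame.

    Replacement values are sampled with replacement from the *original*
    frame's intensity multiset, so the replaced values are plausible but
    carry no information about the true value at the blind location.
    """
    frame = np.asarray(frame)
    H, W = frame.shape
    coords = mask.coordinates
    if len(coords) and (
        coords[:, 0].min() < 0 or coords[:, 0].max() >= H
        or coords[:, 1].min() < 0 or coords[:, 1].max() >= W
    ):
        raise ValueError("blind-mask coordinate out of frame bounds")
    out = frame.copy()
    if len(coords):
        src = rng.integers(0, H * W, size=len(coords))
        out[coords[:, 0], coords[:, 1]] = frame.ravel()[src]
    return out


def _assemble(
    data: np.ndarray,
    t: int,
    n_frames: int,
    prior_channels: np.ndarray,
    degraded_center: Optional[np.ndarray] = None,
) -> np.ndarray:
    T = data.shape[0]
    n0 = n_frames // 2
    idx = reflect_indices(np.arange(t - n0, t + n0 + 1), T)
    frames = data[idx].astype(np.float64, copy=True)
    if degraded_center is not None:
        frames[n0] = degraded_center
    return np.concatenate([frames, prior_channels], axis=0)


def assemble_input(
    video: VideoStack,
    t: int,
    prior: PriorStack,
    n_frames: int = 7,
    mask: Optional[BlindMask] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Stack the main-branch input channels for frame t (unnormalized).

    Channel order: frames t-N0 ... t-1, the central frame (degraded if a
    blind mask is given), frames t+1 ... t+N0, then the prior channels.
    Frame indices reflect at the video ends. Returns an (N + C_prior, H, W)
    array.
    """
    if prior.center_index != t:
        raise ValueError(f"prior centred on frame {prior.center_index}, expected {t}")
    data = video.data
    if prior.channels.shape[1:] != data.shape[1:]:
        raise ValueError(
            f"prior spatial shape {prior.channels.shape[1:]} does not match "
            f"video frames {data.shape[1:]}"
        )
    if n_frames < 3 or n_frames % 2 == 0:
        raise ValueError("n_frames must be odd and >= 3")
    degraded = None
    if mask is not None and len(mask):
        if rng is None:
            raise ValueError("an rng is required to draw blind-pixel replacements")
        degraded = apply_blind_pixels(data[t], mask, rng)
    return _assemble(data, t, n_frames, prior.channels, degraded)


def masked_mse(prediction: np.ndarray, target: np.ndarray, mask: BlindMask) -> float:
    """Mean squared error over the blind coordinates only.

    The target is the original (pre-replacement) noisy central frame.
    """
    if len(mask) == 0:
        raise ValueError("masked MSE is undefined for an empty blind mask")
    r, c = mask.coordinates[:, 0], mask.coordinates[:, 1]
    diff = np.asarray(prediction)[r, c] - np.asarray(target)[r, c]
    return float(np.mean(diff**2))


def masked_mse_grad(
    prediction: np.ndarray, target: np.ndarray, mask: BlindMask
) -> np.ndarray:
    """Gradient of :func:`masked_mse` w.r.t. the prediction.

    Exactly zero everywhere except at the blind coordinates — perturbing any
    non-blind pixel of prediction or target cannot move the loss.
    """
    if len(mask) == 0:
        raise ValueError("masked MSE is undefined for an empty blind mask")
    r, c = mask.coordinates[:, 0], mask.coordinates[:, 1]
    grad = np.zeros_like(np.asarray(prediction, dtype=np.float64))
    grad[r, c] = 2.0 * (np.asarray(prediction)[r, c] - np.asarray(target)[r, c]) / len(mask)
    return grad


def _standardize_channels(channels: np.ndarray) -> np.ndarray:
    """Zero-mean unit-SD per channel; constant channels map to zero."""
    out = np.empty_like(channels, dtype=np.float64)
    for i, ch in enumerate(channels):
        sd = ch.std()
        out[i] = (ch - ch.mean()) / sd if sd > 0 else 0.0
    return out


def _prior_channels_for(
    data: np.ndarray, t: int, spec: ModelSpec, m_frames: Union[int, str]
) -> np.ndarray:
    """Raw prior channels for frame t of a (T,H,W) array."""
    mean = local_mean_frame(VideoStack(data, frame_rate=1.0), t, m_frames)
    if spec.variant == "M":
        return mean[None]
    return edge_channels(mean, spec.blur_sigma)


class _SampleBuilder:
    """Builds normalized training/inference samples from one video."""

    def __init__(self, data: np.ndarray, spec: ModelSpec, norm_mean: float, norm_sd: float):
        self.data = data
        self.spec = spec
        self.norm_mean = norm_mean
        self.norm_sd = norm_sd
        self._global_mean: Optional[np.ndarray] = None

    @property
    def global_mean(self) -> np.ndarray:
        if self._global_mean is None:
            self._global_mean = self.data.mean(axis=0)
        return self._global_mean

    def normalize_frames(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.norm_mean) / self.norm_sd

    def build(
        self,
        t: int,
        window: tuple[slice, slice],
        mask: Optional[BlindMask],
        rng: Optional[np.random.Generator],
        m_frames: Optional[Union[int, str]] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (input channels, normalized original central patch)."""
        ys, xs = window
        patch = self.data[:, ys, xs]
        m = self.spec.m_frames if m_frames is None else m_frames
        if m == "all":
            mean = self.global_mean[ys, xs]
            prior = mean[None] if self.spec.variant == "M" else edge_channels(mean, self.spec.blur_sigma)
        else:
            prior = _prior_channels_for(patch, t, self.spec, m)
        center = patch[t].astype(np.float64)
        degraded = apply_blind_pixels(center, mask, rng) if mask is not None and len(mask) else None
        n0 = self.spec.n_frames // 2
        idx = reflect_indices(np.arange(t - n0, t + n0 + 1), patch.shape[0])
        frames = patch[idx].astype(np.float64, copy=True)
        if degraded is not None:
            frames[n0] = degraded
        x = np.concatenate([self.normalize_frames(frames), _standardize_channels(prior)], axis=0)
        return x, self.normalize_frames(center)


def train(
    source,
    spec: ModelSpec,
    config: TrainConfig,
) -> tuple[TrainedModel, TrainingHistory]:
    """Self-supervised training on a single video (or bundle's noisy video).

    Random square patches are drawn from training frames; each sample masks
    p_blind of the central patch's pixels and the loss is the masked MSE
    against the original noisy patch. Stops after ``dataset_passes`` passes
    over the training frames (one sample = one frame draw) or ``max_steps``.
    """
    video: VideoStack = source.noisy if hasattr(source, "noisy") else source
    data = np.asarray(video.data, dtype=np.float64)
    T, H, W = data.shape
    if T < spec.n_frames:
        raise ValueError(f"video has {T} frames but the input window needs {spec.n_frames}")
    if spec.p_blind <= 0:
        raise ValueError("p_blind must be > 0 to train: the masked loss is undefined otherwise")

    norm_mean = float(data.mean())
    norm_sd = float(data.std())
    if norm_sd == 0:
        raise ValueError("cannot normalize a constant video")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_mask, rng_replace, rng_patch, rng_val = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    net = DenoiserNet(spec.input_channels, spec.feature_width, spec.n_res_blocks,
                      spec.kernel_size, rng_init)
    builder = _SampleBuilder(data, spec, norm_mean, norm_sd)

    # validation frames held out from patch sampling
    n_val = int(round(config.val_fraction * T))
    if n_val > 0:
        val_idx = np.unique(np.linspace(0, T - 1, n_val).round().astype(int))
        train_idx = np.setdiff1d(np.arange(T), val_idx)
    else:
        val_idx = np.array([], dtype=int)
        train_idx = np.arange(T)
    if len(train_idx) == 0:
        raise ValueError("no training frames left after the validation split")

    ps = min(config.patch_size, H, W)

    def _window(rng) -> tuple[slice, slice]:
        y0 = int(rng.integers(0, H - ps + 1))
        x0 = int(rng.integers(0, W - ps + 1))
        return slice(y0, y0 + ps), slice(x0, x0 + ps)

    # fixed validation samples so the plateau rule sees a stable quantity
    val_samples = []
    for t in (val_idx if len(val_idx) else train_idx[:1]):
        win = _window(rng_val)
        mask = sample_blind_mask((ps, ps), spec.p_blind, rng_val)
        x, target = builder.build(int(t), win, mask, rng_val)
        val_samples.append((x, target, mask))
    val_samples = val_samples[:8]

    total_samples = config.dataset_passes * len(train_idx)
    total_steps = math.ceil(total_samples / config.batch_size)
    if config.max_steps is not None:
        total_steps = min(total_steps, config.max_steps)
    window_steps = max(1, math.ceil(config.plateau_window_samples / config.batch_size))
    val_every = max(1, window_steps // 8)

    lr = config.lr_init
    opt = Adam(net.params(), lr)
    history = TrainingHistory()
    window_val: list[float] = []
    prev_window: Optional[float] = None
    samples_seen = 0

    def _val_loss() -> float:
        losses = []
        for x, target, mask in val_samples:
            pred = net.forward(x[None], training=False)[0, 0]
            losses.append(masked_mse(pred, target, mask))
        return float(np.mean(losses))

    for step in range(total_steps):
        xs, targets, masks = [], [], []
        for _ in range(config.batch_size):
            t = int(train_idx[rng_patch.integers(0, len(train_idx))])
            win = _window(rng_patch)
            mask = sample_blind_mask((ps, ps), spec.p_blind, rng_mask)
            x, target = builder.build(t, win, mask, rng_replace)
            xs.append(x)
            targets.append(target)
            masks.append(mask)
        batch = np.stack(xs)
        pred = net.forward(batch, training=True)

        B = config.batch_size
        loss = 0.0
        dpred = np.zeros_like(pred)
        for i, mask in enumerate(masks):
            loss += masked_mse(pred[i, 0], targets[i], mask)
            dpred[i, 0] = masked_mse_grad(pred[i, 0], targets[i], mask) / B
        loss /= B

        net.zero_grad()
        net.backward(dpred)
        opt.lr = lr
        opt.step(net.grads())

        samples_seen += B
        history.train_loss.append(loss)
        history.lr.append(lr)
        history.samples_seen.append(samples_seen)

        if (step + 1) % val_every == 0 or step == total_steps - 1:
            window_val.append(_val_loss())
        # plateau check at each completed window of plateau_window_samples
        if (step + 1) % window_steps == 0 and window_val:
            wmean = float(np.mean(window_val))
            history.val_windows.append((samples_seen, wmean))
            if prev_window is not None and wmean > prev_window * (1 - config.plateau_improve_tol):
                if lr > config.lr_min:
                    lr = max(lr / 2.0, config.lr_min)
                    history.lr_events.append((samples_seen, lr))
            prev_window = wmean
            window_val = []

    model = TrainedModel(net=net, spec=spec, norm_mean=norm_mean, norm_sd=norm_sd)
    return model, history


def denoise_video(
    model: TrainedModel,
    video: VideoStack,
    mode: str = "offline",
    chunk_size: int = 16,
) -> VideoStack:
    """Denoise every frame of a video with a trained model.

    No blind pixels are applied at inference: the raw central frame enters
    the network. ``offline`` mode builds the spatial prior from the global
    mean (M = all); ``online`` mode uses the model's finite M window, which
    bounds latency to max(N0, M0) frames, and requires a model trained with
    a finite M.
    """
    if mode not in ("offline", "online"):
        raise ValueError(f"mode must be 'offline' or 'online'; got {mode!r}")
    spec = model.spec
    if mode == "online" and spec.m_frames == "all":
        raise ValueError("online mode needs a model with a finite m_frames window")
    m_frames: Union[int, str] = "all" if mode == "offline" else spec.m_frames

    data = np.asarray(video.data, dtype=np.float64)
    T, H, W = data.shape
    builder = _SampleBuilder(data, spec, model.norm_mean, model.norm_sd)
    full = (slice(0, H), slice(0, W))
    out = np.empty_like(data)
    for start in range(0, T, chunk_size):
        idx = range(start, min(start + chunk_size, T))
        batch = np.stack([builder.build(t, full, None, None, m_frames=m_frames)[0] for t in idx])
        pred = model.net.forward(batch, training=False)[:, 0]
        out[list(idx)] = pred * model.norm_sd + model.norm_mean
    return video.with_data(out)
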