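"""Spatial-prior extraction: windowed mean frames and directional edges.

The side branch of the denoiser builds a spatial prior for each target
frame: the mean of M = 2*M0 + 1 frames centred on it ("all" means the
global temporal mean). The edge variant (E) then Gaussian-blurs the mean
frame and extracts four directional Sobel edge maps (0, 45, 90, 135
degrees) which enter the network as four extra channels; the mean variant
(M) feeds the mean frame in directly as one extra channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.ndimage import correlate, gaussian_filter

from .video import VideoStack

__all__ = [
    "PriorStack",
    "SOBEL_KERNELS",
    "local_mean_frame",
    "edge_channels",
    "build_prior",
    "reflect_indices",
]

# 3x3 Sobel kernels by gradient direction. 0 deg responds to horizontal
# gradients (vertical edges); 90 deg is its transpose; the diagonals are the
# standard 45/135-degree rotations.
SOBEL_KERNELS: dict[int, np.ndarray] = {
    0: np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),
    45: np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float),
    90: np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float),
    135: np.array([[-2, -1, 0], [-1, 0, 1], [0, 1, 2]], dtype=float),
}


@dataclass
class PriorStack:
    """Per-frame spatial-prior channels (4 edge maps for E, 1 mean for M)."""

    channels: np.ndarray  # (C, H, W)
    variant: str  # "E" or "M"
    m_frames: Union[int, str]  # odd int or "all"
    center_index: int

    def __post_init__(self) -> None:
        expected = 4 if self.variant == "E" else 1
        if self.channels.shape[0] != expected:
            raise ValueError(
                f"variant {self.variant} expects {expected} channels; "
                f"got {self.channels.shape[0]}"
            )
        if not np.isfinite(self.channels).all():
            raise ValueError("prior channels must be finite")


def reflect_indices(indices: np.ndarray, n: int) -> np.ndarray:
    """Map arbitrary integer indices into [0, n) by boundary reflection.

    Reflection is without edge repetition (index -1 maps to 1, n maps to
    n - 2), matching numpy's ``pad(mode='reflect')``.
    """
    if n == 1:
        return np.zeros_like(indices)
    period = 2 * n - 2
    idx = np.mod(indices, period)
    return np.where(idx >= n, period - idx, idx)


def local_mean_frame(
    video: VideoStack, t: int, m_frames: Union[int, str]
) -> np.ndarray:
    """Mean of the M frames centred on t (reflected at the video ends).

    ``m_frames="all"`` returns the global temporal mean regardless of t.
    """
    data = video.data
    T = data.shape[0]
    if not 0 <= t < T:
        raise ValueError(f"frame index {t} outside [0, {T})")
    if isinstance(m_frames, str):
        if m_frames != "all":
            raise ValueError(f"m_frames must be an odd int or 'all'; got {m_frames!r}")
        return data.mean(axis=0)
    if m_frames < 1 or m_frames % 2 == 0:
        raise ValueError(f"m_frames must be odd and >= 1; got {m_frames}")
    m0 = m_frames // 2
    idx = reflect_indices(np.arange(t - m0, t + m0 + 1), T)
    return data[idx].mean(axis=0)


def edge_channels(mean_frame: np.ndarray, blur_sigma: float = 1.0) -> np.ndarray:
    """Gaussian blur then four directional Sobel maps, order (0, 45, 90, 135).

    ``blur_sigma=0`` disables the blur. Reflect boundary handling throughout
    so edge responses do not depend on the frame border.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    frame = np.asarray(mean_frame, dtype=np.float64)
    if not np.isfinite(frame).all():
        raise ValueError("mean frame must be finite")
    blurred = gaussian_filter(frame, blur_sigma, mode="reflect") if blur_sigma > 0 else frame
    return np.stack(
        [correlate(blurred, SOBEL_KERNELS[a], mode="reflect") for a in (0, 45, 90, 135)]
    )


def build_prior(
    video: VideoStack,
    t: int,
    variant: str,
    m_frames: Union[int, str],
    blur_sigma: float = 1.0,
) -> PriorStack:
    """Assemble the side-branch output for frame t.

    Variant M: one channel, the raw local mean frame (no blur, no Sobel).
    Variant E: four channels, the directional edge maps of the blurred mean.
    """
    if variant not in ("E", "M"):
        raise ValueError(f"variant must be 'E' or 'M'; got {variant!r}")
    mean = local_mean_frame(video, t, m_frames)
    if variant == "M":
        channels = mean[None, :, :]
    else:
        channels = edge_channels(mean, blur_sigma)
    return PriorStack(channels=channels, variant=variant, m_frames=m_frames, center_index=t)
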