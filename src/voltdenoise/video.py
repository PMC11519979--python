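"""Core containers for time-series fluorescence imaging data.

A :class:`VideoStack` is the universal currency of the pipeline: a T x H x W
array of non-negative intensities together with the acquisition metadata
(frame rate, physical pixel sizes) needed to express results in physical
units (seconds, micrometres).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Acquisition defaults for kilohertz-rate two-photon voltage imaging:
#: 803 Hz sampling with anisotropic 1.0 um x 2.1 um pixels.
DEFAULT_FRAME_RATE = 803.0
DEFAULT_PIXEL_SIZE_X = 1.0
DEFAULT_PIXEL_SIZE_Y = 2.1


@dataclass
class VideoStack:
    """A T-frame video of H x W intensity values plus physical metadata.

    Parameters
    ----------
    data:
        Array of shape (T, H, W); non-negative intensities (photon counts or
        detector units).
    frame_rate:
        Acquisition rate in Hz.
    pixel_size_x, pixel_size_y:
        Physical pixel dimensions in micrometres. Anisotropic pixels are
        carried as metadata; all geometry is done on the pixel grid.
    """

    data: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    pixel_size_x: float = DEFAULT_PIXEL_SIZE_X
    pixel_size_y: float = DEFAULT_PIXEL_SIZE_Y

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"video data must be 3-D (T, H, W); got shape {self.data.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame i is acquired at i / rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def with_data(self, data: np.ndarray) -> "VideoStack":
        """New stack sharing this stack's metadata."""
        return replace(self, data=np.asarray(data))


@dataclass
class ROISet:
    """Regions of interest as an integer label map (0 = background)."""

    label_map: np.ndarray
    roi_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D")
        found = sorted(int(v) for v in np.unique(self.label_map) if v != 0)
        if not self.roi_ids:
            self.roi_ids = found
        else:
            missing = [i for i in self.roi_ids if i not in found]
            if missing:
                raise ValueError(f"ROI ids {missing} are empty in the label map")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("ROI ids must be unique")

    def mask(self, roi_id: int) -> np.ndarray:
        m = self.label_map == roi_id
        if not m.any():
            raise ValueError(f"ROI {roi_id} is empty")
        return m

    def __len__(self) -> int:
        return len(self.roi_ids)
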