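"""File I/O: TIFF stacks, ROI label maps, CSV tables, JSON/YAML configs.

Videos travel as multi-page TIFF with the acquisition metadata (frame rate,
pixel sizes) embedded in the ImageDescription tag as JSON, so a stack
round-trips losslessly through disk together with its physical units.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simdata import GroundTruthBundle
from .video import (
    DEFAULT_FRAME_RATE,
    DEFAULT_PIXEL_SIZE_X,
    DEFAULT_PIXEL_SIZE_Y,
    ROISet,
    VideoStack,
)

__all__ = [
    "read_stack",
    "write_stack",
    "read_roi_map",
    "write_roi_map",
    "write_bundle",
    "read_bundle",
    "write_spikes_csv",
    "read_spikes_csv",
    "load_config",
    "save_config",
]


def write_stack(video: VideoStack, path) -> None:
    """Write a video as multi-page TIFF with metadata in the description.

    Integer-valued data are stored as 16-bit unsigned (bit-exact roundtrip);
    anything else as 32-bit float.
    """
    path = Path(path)
    data = video.data
    if np.issubdtype(data.dtype, np.integer) or (
        np.all(data >= 0) and np.all(data == np.rint(data)) and data.max(initial=0) < 2**16
    ):
        out = data.astype(np.uint16)
    else:
        out = data.astype(np.float32)
    meta = {
        "frame_rate": video.frame_rate,
        "pixel_size_x": video.pixel_size_x,
        "pixel_size_y": video.pixel_size_y,
    }
    tifffile.imwrite(path, out, description=json.dumps(meta), photometric="minisblack")


def read_stack(path) -> VideoStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Missing metadata falls back (with a warning) to the 803-Hz,
    1.0 x 2.1 um acquisition defaults.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # corrupt or unreadable file
        raise IOError(f"cannot read TIFF stack at {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a T x H x W stack, got shape {data.shape}")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if "frame_rate" not in meta:
        warnings.warn(
            f"{path}: no acquisition metadata found; assuming "
            f"{DEFAULT_FRAME_RATE} Hz and {DEFAULT_PIXEL_SIZE_X} x "
            f"{DEFAULT_PIXEL_SIZE_Y} um pixels",
            stacklevel=2,
        )
    return VideoStack(
        data.astype(np.float64),
        frame_rate=float(meta.get("frame_rate", DEFAULT_FRAME_RATE)),
        pixel_size_x=float(meta.get("pixel_size_x", DEFAULT_PIXEL_SIZE_X)),
        pixel_size_y=float(meta.get("pixel_size_y", DEFAULT_PIXEL_SIZE_Y)),
    )


def write_roi_map(rois: ROISet, path) -> None:
    tifffile.imwrite(Path(path), rois.label_map.astype(np.uint16))


def read_roi_map(path) -> ROISet:
    labels = tifffile.imread(Path(path))
    return ROISet(labels.astype(np.int32))


def write_spikes_csv(spike_times: dict[int, np.ndarray], path) -> None:
    rows = [
        {"roi_id": roi_id, "time_s": float(t)}
        for roi_id, times in spike_times.items()
        for t in np.atleast_1d(times)
    ]
    pd.DataFrame(rows, columns=["roi_id", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(roi_id): grp["time_s"].to_numpy()
        for roi_id, grp in df.groupby("roi_id")
    }


def write_bundle(bundle: GroundTruthBundle, out_dir) -> None:
    """Persist a synthetic bundle: TIFFs + CSV tables + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(bundle.noisy, out / "noisy.tif")
    write_stack(bundle.clean, out / "clean.tif")
    write_roi_map(bundle.rois, out / "rois.tif")
    write_spikes_csv(bundle.spike_times, out / "spikes.csv")
    pd.DataFrame({"time_s": bundle.stimulus_onsets}).to_csv(
        out / "stimuli.csv", index=False
    )
    manifest = {
        "gain": bundle.gain,
        "n_frames": bundle.noisy.n_frames,
        "frame_rate": bundle.noisy.frame_rate,
        "n_rois": len(bundle.rois),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_bundle(in_dir) -> GroundTruthBundle:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    return GroundTruthBundle(
        clean=read_stack(src / "clean.tif"),
        noisy=read_stack(src / "noisy.tif"),
        rois=read_roi_map(src / "rois.tif"),
        spike_times=read_spikes_csv(src / "spikes.csv"),
        stimulus_onsets=pd.read_csv(src / "stimuli.csv")["time_s"].to_numpy(),
        gain=float(manifest["gain"]),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
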