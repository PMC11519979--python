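"""Photon-noise characterisation and photon-level degradation.

In the low-photon regime the detector signal is shot-noise dominated: the
temporal variance of each pixel is proportional to its temporal mean, and
the constant of proportionality, beta, characterises the imaging system
(it equals the detector gain under pure Poisson statistics). Lower-photon
versions of a video can then be simulated by a two-step protocol that
preserves beta:

1. binomial thinning, ``Ib ~ Binomial(I0, p)``, which reduces intensity but
   also lowers the variance-to-mean ratio to ``beta_b = p*beta_0 + (1-p)``;
2. a global rescale by ``A = beta_0 / beta_b``, which restores the ratio and
   leaves the video at an effective photon-level fraction ``d = p*A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video import VideoStack

__all__ = ["NoiseCharacter", "DegradationSpec", "estimate_beta", "degrade_photon_level"]


@dataclass
class NoiseCharacter:
    """Variance-to-mean ratio of a video and the quality of its fit.

    ``beta`` is the slope of a through-origin least-squares fit of per-pixel
    temporal variance against per-pixel temporal mean; ``fit_quality`` is
    the coefficient of determination of that fit (1 for exact
    proportionality), useful for spotting violations such as read noise.
    """

    beta: float
    n_pixels_used: int
    fit_quality: float


@dataclass
class DegradationSpec:
    """Parameters of one two-step photon-level degradation."""

    p: float  # binomial survival probability
    beta0: float  # variance-to-mean ratio of the input
    betab: float  # ratio after thinning
    A: float  # rescale factor beta0 / betab
    d: float  # effective photon-level fraction p * A


def estimate_beta(video: VideoStack) -> NoiseCharacter:
    """Fit the per-pixel temporal variance against the temporal mean.

    Pixels whose temporal mean is zero carry no information about the gain
    and are excluded. The fit is through the origin (pure shot-noise model,
    no read-noise intercept).
    """
    data = np.asarray(video.data, dtype=np.float64)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames to estimate variance")
    mean = data.mean(axis=0).ravel()
    var = data.var(axis=0, ddof=1).ravel()
    keep = mean > 0
    if not keep.any():
        raise ValueError("no informative pixels: all pixels have zero mean")
    m, v = mean[keep], var[keep]
    beta = float(np.dot(m, v) / np.dot(m, m))
    ss_res = float(np.sum((v - beta * m) ** 2))
    ss_tot = float(np.sum(v**2))
    quality = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NoiseCharacter(beta=beta, n_pixels_used=int(keep.sum()), fit_quality=quality)


def degrade_photon_level(
    video: VideoStack, p: float, rng_seed: int
) -> tuple[VideoStack, DegradationSpec]:
    """Simulate the video at a lower photon level, preserving beta.

    Intensities are rounded to the nearest integer before thinning (raw
    counts are integer-valued in the low-photon regime, so the rounding
    error is below one quantum). With ``p == 1`` the input is returned
    unchanged.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1]; got {p}")
    data = np.asarray(video.data)
    if (data < 0).any():
        raise ValueError("video intensities must be non-negative")

    beta0 = estimate_beta(video).beta
    if p == 1.0:
        spec = DegradationSpec(p=1.0, beta0=beta0, betab=beta0, A=1.0, d=1.0)
        return video.with_data(data.copy()), spec

    rng = np.random.default_rng(rng_seed)
    trials = np.rint(data).astype(np.int64)
    thinned = rng.binomial(trials, p).astype(np.float64)
    thinned_stack = video.with_data(thinned)
    betab = estimate_beta(thinned_stack).beta
    if betab == 0:
        raise ValueError("degenerate video: thinned stack has zero variance-to-mean ratio")
    A = beta0 / betab
    degraded = video.with_data(A * thinned)
    spec = DegradationSpec(p=p, beta0=beta0, betab=betab, A=A, d=p * A)
    return degraded, spec
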