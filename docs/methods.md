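# Methods

This note documents the models, algorithms and numerical choices behind
`voltdenoise`, and what the synthetic benchmark does and does not show.

## Problem setting

Two-photon voltage imaging acquires kilohertz-rate movies of genetically
encoded voltage indicators. At 803 Hz with microsecond dwell times the
photon budget per pixel per frame is tiny — nearly all raw readouts are
below 10 counts — so the data are dominated by Poisson shot noise: the
temporal variance of each pixel is proportional to its temporal mean, with
slope beta equal to the effective detector gain. Denoising must recover
both fine spatial structure (membranes a few pixels wide) and millisecond
transients (stimulus-evoked potentials), without any clean reference data.

## Self-supervised denoising model

The denoiser predicts each frame from its spatiotemporal context. Its
input for target frame *t* stacks:

- **N = 2·N0+1 consecutive frames** centred on *t* (default N=7). The
  central frame is *degraded* during training: a random fraction
  `p_blind` (default 0.5%) of its pixels are replaced by values drawn
  uniformly (with replacement) from the same frame's intensity multiset.
- **Spatial-prior channels** from a side branch: the mean of M = 2·M0+1
  frames centred on *t* (M = "all" uses the global mean). The **E
  variant** Gaussian-blurs this mean (sigma 1 px, configurable) and
  appends four 3×3 directional Sobel maps (0°, 45°, 90°, 135°); the **M
  variant** appends the mean frame itself as a single channel.

The network is a residual CNN: a 3×3 lead-in convolution to
`feature_width` channels, four residual blocks (conv–BN–PReLU–conv–BN with
an identity skip), and a 3×3 lead-out convolution to one channel. The
loss is the mean squared error between the output and the *original*
(pre-replacement) noisy central frame, evaluated **only at the blind
pixels**. Since the network never sees a blind pixel's true value, the
identity map gains nothing; minimizing the loss forces genuine inference
from context. At inference nothing is masked and frames are denoised one
by one; "offline" mode builds the prior from the global mean, "online"
mode from the model's finite M window (latency max(N0, M0) frames).

N controls temporal smoothing and M controls spatial-prior fidelity; they
can be tuned independently, which is what decouples temporal from spatial
performance.

### Why the engine is hand-written

No deep-learning framework is assumed: convolutions (im2col + BLAS
matmul), batch normalization, PReLU, backpropagation and Adam are
implemented in numpy in `voltdenoise.nn`, verified against
finite-difference gradients in the test suite. Arrays are float32 by
default (float64 for gradient checks). Convolutions use zero 'same'
padding; the spatial-prior filters use reflect boundaries.

### Training schedule

The default schedule: Adam, batch size 4, 360 steps per
epoch, stop after three passes over the training frames, initial learning
rate 5e-6 halved when the validation loss fails to improve by more than
0.1% between successive windows of 288,000 samples, floored at 1e-7. A 5%
frame hold-out provides the validation loss (evaluated on fixed patches
and masks so the plateau rule sees a stable quantity). Training samples
are random square patches (default 64 px) of random training frames.

That schedule is sized for a corpus of >10^6 samples. Desk-scale runs in
the examples, tests and acceptance script use the same machinery with a
larger learning rate (1e-3–4e-3), 8–16 feature channels and a few hundred
to ~2000 steps on videos of 32–48 px and 2400–2800 frames; these sizes
were chosen so a full run completes in minutes on one CPU while still
exhibiting the method's qualitative behaviour.

## Photon-level degradation

To emulate lower photon budgets, each (integer-rounded) pixel count is
thinned, `Ib ~ Binomial(I0, p)`, which scales the mean by p but drops the
variance-to-mean ratio to `beta_b = p·beta0 + (1−p)`; multiplying by
`A = beta0/beta_b` restores the ratio, leaving the video at an effective
photon fraction `d = p·A`. `estimate_beta` fits variance against mean
through the origin (pure shot-noise model; read noise is deliberately out
of scope) and reports the fit's R² so violations are visible. Rounding
before thinning introduces sub-quantum error only, as raw counts are
integer-valued in this regime.

## Evaluation metrics

- **Trace preprocessing**: ROI trace (mean over ROI pixels) minus a
  centred 2.5-s moving average (reflect-padded), then divided by the mean
  absolute value of the residual, so detection thresholds are in units of
  "typical excursion". Using the residual (rather than the raw trace) as
  the normalizer keeps the threshold meaningful under drift.
- **Spike detection**: peaks above 4 within 0–0.1 s of a stimulus onset,
  minimum separation 0.1 s (larger peak wins), each annotated with its
  FWHM (half-maximum crossings by linear interpolation); events with FWHM
  outside mean ± 3 SD of the detected population are discarded.
- **Temporal SNR**: mean power within spike-width segments (one FWHM
  centred on each peak) divided by the mean power of the entire trace (a
  serviceable noise estimate for sparse signals). When traces are
  *compared* (raw vs denoised), a common segment set must be used or the
  ratio comparison is meaningless; comparisons on synthetic data use
  segments derived from the ground-truth spike times.
- **Spatial metrics**: radially averaged periodogram of a mean-subtracted
  frame in physical units (cycles/μm), honouring anisotropic pixels
  (1.0 × 2.1 μm defaults). Radial bin width is the fundamental frequency
  of the coarser-sampled axis; bins stop at the lower Nyquist limit. The
  noise floor is the mean PSD over the top decile of frequencies
  (fraction configurable); the cutoff is the lowest frequency where the
  PSD does not exceed the floor; resolution = 1/cutoff; spatial SNR =
  power below cutoff / power above.
- **PCC**: Pearson correlation against the temporal-average frame
  (spatial) or a 7-frame moving average of the raw trace (temporal); on
  synthetic data the noise-free ground truth replaces these references.
- **SNR split**: fields of view sorted by mean ROI temporal SNR; bottom
  half low, top half high; with an odd count the median joins the low
  subset; ties break stably on FOV id.

## Synthetic data generator

The generator reproduces the statistical structure the method assumes,
with known ground truth:

- **Scene**: annular "membrane" neurons (outer radius 4–7 px, thickness
  1–2 px) on a dim background with a gentle illumination gradient.
  Defaults: background ≈ 0.5 counts, membrane ≈ 4 counts at unit gain, so
  ≥99% of readouts are below 10 counts.
- **Activity**: air-puff stimulus trains (5 puffs at 10 Hz, repeated
  every 4 s) evoke positive-going spikes in each neuron with probability
  0.9 per puff, at 10–60 ms latency, amplitude ~0.4 ΔF/F (jittered ±20%).
  Spikes are asymmetric double-exponentials with 10 ms FWHM. Continuous
  subthreshold fluctuations (0.08 ΔF/F, ~10 ms correlation time) are
  always present.
- **Noise**: counts are `gain × Poisson(clean)`, giving variance/mean =
  gain exactly.

Two generator choices deserve justification. First, the 10 ms evoked-
potential width: a transient much narrower than the N=7 input window
cannot survive *any* denoiser that pools 7 frames, whereas the method is
known to preserve spike widths at N=7 and to over-smooth only at much
larger N — behaviour only consistent with evoked potentials spanning at
least ~N frames (≳9 ms at 803 Hz), which also matches typical GEVI evoked
responses. Second, the nonzero subthreshold activity: with a perfectly
static scene plus white shot noise, the self-supervised optimum is pure
temporal averaging and no method could demonstrate temporal fidelity;
real membrane potential fluctuates continuously, and including that makes
temporal tracking identifiable.

What the generator does **not** model: optics (no PSF), motion or drift,
hemodynamic artifacts, mosaic stitching seams, read noise or gain maps.
Passing tests therefore demonstrate the pipeline's correctness and the
method's qualitative behaviour in a shot-noise-limited, motion-free
regime — not performance on real in vivo recordings.

## Numerical choices and degenerate inputs

- Temporal windows reflect at video ends (no edge repetition); spatial
  filters reflect at frame borders.
- Prior channels are standardized (zero mean, unit SD per channel) before
  entering the network; video channels are normalized by the training
  video's global mean/SD, stored in the checkpoint and inverted on output.
- Constant videos cannot be trained on (zero normalization SD) and
  constant traces raise rather than return NaNs; an all-zero-mean video
  has no estimable beta.
- `p_blind = 0` refuses to train (the masked loss is undefined).
- Blind-mask size is `round(p_blind · H · W)` distinct coordinates.
- The FWHM of a single-sample impulse is one sample by linear
  interpolation; events whose flanks never reach half-maximum are
  discarded with a warning.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; full-scale videos
  (400×192 × 10^3 frames, 64 features) are out of desk reach. The
  architecture and schedule are nonetheless faithful, and every component
  scales down without modification.
- Desk-scale training (10^3–10^4 samples) reaches the regime where
  denoising gains are measurable but spike amplitudes are partially
  shrunk (the MSE-optimal estimator of sparse transients shrinks them
  toward the mean at these SNRs); quantitative spike-amplitude retention
  should not be read off these runs.
- The PSD noise-floor estimate assumes noise dominates the top decile of
  spatial frequencies; heavily oversampled optics would violate this. The
  spatial SNR of a single frame is sensitive to where the PSD first meets
  the floor, so comparative evaluations average it over several frames.
- At the generator's default membrane brightness, a 7-frame mean followed
  by the sigma-1 blur already yields a high-SNR spatial prior, so the
  spatial-prior window M has little measurable effect on desk-scale
  denoised frames: the decoupling checks reproduce the over-smoothing of
  detected spikes at large N, but not the spatial plateau in M, which
  requires a prior-noise-limited regime (dimming the scene enough to
  reach that regime makes desk-scale training collapse entirely).
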