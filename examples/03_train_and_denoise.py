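"""Train the self-supervised denoiser on a synthetic recording and measure
the improvement against the known ground truth.

Uses the edge-prior variant (v2-E) with a 7-frame temporal window and a
31-frame spatial-prior window — the online-capable configuration — at a
desk-friendly scale (16 feature channels, ~5 minutes on one CPU).
"""

import numpy as np

from voltdenoise import (
    ModelSpec,
    SimConfig,
    TrainConfig,
    denoise_video,
    generate_dataset,
    pcc,
    train,
)

bundle = generate_dataset(
    SimConfig(height=48, width=48, neuron_count=4, duration_s=3.0), rng_seed=7
)

spec = ModelSpec(n_frames=7, m_frames=31, variant="E", feature_width=16)
config = TrainConfig(lr_init=2e-3, patch_size=48, seed=1, max_steps=1200,
                     plateau_window_samples=1600)
model, history = train(bundle.noisy, spec, config)
print(f"trained {len(history.train_loss)} steps; masked-MSE "
      f"{np.mean(history.train_loss[:40]):.3f} -> {np.mean(history.train_loss[-40:]):.3f}")

denoised = denoise_video(model, bundle.noisy, mode="offline")

for rid in bundle.rois.roi_ids:
    m = bundle.rois.mask(rid)
    clean_tr = bundle.clean.data[:, m].mean(1)
    raw_tr = bundle.noisy.data[:, m].mean(1)
    den_tr = denoised.data[:, m].mean(1)
    print(f"ROI {rid}: temporal PCC vs ground truth  "
          f"raw {pcc(raw_tr, clean_tr):.3f} -> denoised {pcc(den_tr, clean_tr):.3f}")
# the denoised trace correlates substantially better with the noise-free
# ground truth than the raw trace does, for every neuron.
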