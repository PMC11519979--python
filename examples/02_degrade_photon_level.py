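"""Simulate a recording at a lower photon level without changing beta.

The two-step protocol thins each (integer) pixel count with a binomial
draw, which lowers both the intensity and the variance-to-mean ratio, then
rescales by A = beta0/beta_b to restore the ratio. The video ends up at an
effective photon fraction d = p*A of the original.
"""

from voltdenoise import SimConfig, degrade_photon_level, estimate_beta, generate_dataset

bundle = generate_dataset(SimConfig(duration_s=3.0, gain=2.0), rng_seed=2)
video = bundle.noisy
beta0 = estimate_beta(video).beta
print(f"original: mean intensity {video.data.mean():.3f}, beta = {beta0:.3f}")

for p in (0.3, 0.5, 0.7):
    degraded, spec = degrade_photon_level(video, p=p, rng_seed=3)
    beta_d = estimate_beta(degraded).beta
    print(f"p={p:.1f}: beta_b={spec.betab:.3f}  A={spec.A:.3f}  d={spec.d:.3f}  "
          f"mean ratio={degraded.data.mean() / video.data.mean():.3f}  "
          f"beta after={beta_d:.3f}")
# 'mean ratio' tracks d (the photon-level fraction) while 'beta after'
# stays at beta0: dimmer data, same detector statistics.
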