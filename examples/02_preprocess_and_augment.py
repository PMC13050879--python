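"""Preprocessing and S&R augmentation on one training split.

Band-pass 0.5-30 Hz, per-fragment z-scoring, then segmentation-and-
reconstruction: trials are cut into 8 ordered slots and recombined within
class, with bounded Gaussian noise on the new trials.
"""

import numpy as np

from apcformer import (
    AugmentConfig,
    PreprocConfig,
    SyntheticSpec,
    bandpass,
    build_augmented_train_set,
    generate,
    zscore,
)

epochs = generate(SyntheticSpec(n_trials_per_class=30, n_classes=2, snr=1.0,
                                seed=2))
filtered = bandpass(epochs, PreprocConfig())
normalized = zscore(filtered)
print(f"after z-scoring: per-fragment mean {normalized.data.mean(-1).max():.1e} "
      f"(should be ~0), std {normalized.data.std(-1, ddof=1).mean():.6f} "
      f"(should be 1)")

normalized.meta["split"] = "train"
cfg = AugmentConfig(n_segments=8, noise_sigma=0.2, multiplier=1, seed=3)
augmented = build_augmented_train_set(normalized, cfg)
print(f"augmentation: {normalized.n_trials} -> {augmented.n_trials} trials, "
      f"class counts {augmented.class_counts().tolist()}")
print(f"slot length: {normalized.n_samples // cfg.n_segments} samples "
      f"({cfg.n_segments} ordered slots per 4 s trial)")
delta_bound = 1.0
print(f"injected noise is clipped to +/-{delta_bound} in z-scored units, so "
      "augmented trials stay on the scale of the originals")
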