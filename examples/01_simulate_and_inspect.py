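"""Generate synthetic motor-imagery EEG and check its class structure.

Builds a two-class set (10 Hz "mu" effect on C4 vs C3 over 1/f background),
saves it as a bundle, and scores a simple band-power baseline to show the
classes are separable by construction.
"""

import tempfile
from pathlib import Path

from apcformer import SyntheticSpec, bandpower_baseline, generate, load_bundle, save_bundle

spec = SyntheticSpec(n_trials_per_class=40, n_classes=2, snr=2.0, seed=1)
epochs = generate(spec)
print(f"generated {epochs.n_trials} trials x {epochs.n_channels} channels "
      f"x {epochs.n_samples} samples at {epochs.fs:.0f} Hz")
print(f"class counts: {epochs.class_counts().tolist()}")

with tempfile.TemporaryDirectory() as tmp:
    bundle = save_bundle(epochs, Path(tmp) / "bundle")
    reloaded = load_bundle(bundle)
    print(f"bundle round-trip exact: {reloaded == epochs}")

acc = bandpower_baseline(epochs)
print(f"band-power nearest-centroid accuracy: {acc:.2f}")
print("(~1.0 means the mu/beta-band class effect is cleanly recoverable; "
      "0.5 would be chance for two classes)")
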