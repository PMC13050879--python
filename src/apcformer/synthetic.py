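"""Synthetic motor-imagery-like EEG with controllable class structure.

Each trial is 1/f^alpha background noise on every channel; the class effect
is a band-limited oscillation at that class's rhythm frequency (mu ~ 10 Hz,
beta ~ 22 Hz by default), Hann-windowed over the trial and added only on
the class's designated channels.  ``snr`` sets the amplitude ratio between
the effect (on its channels) and the background, and ``erd_depth`` scales
the effect further, so ``snr=0`` or ``erd_depth=0`` collapses all classes
onto the same distribution.

This is a caricature of sensorimotor rhythms, not a forward model: there is
no volume conduction, no artifacts, and the "ERD" is an additive windowed
oscillation rather than suppression of an ongoing rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .data import ChannelSubset, EEGEpochSet

#: Default class -> (rhythm frequency Hz, effect channels) for up to 4 classes,
#: loosely mimicking contralateral mu ERD for left/right hand and midline
#: beta/mu for feet/tongue.
_DEFAULT_EFFECTS = [
    (10.0, ("C4",)),
    (10.0, ("C3",)),
    (22.0, ("Cz",)),
    (22.0, ("C3", "C4")),
]


@dataclass
class SyntheticSpec:
    """Recipe for one labeled synthetic epoch set."""

    n_trials_per_class: int = 50
    n_classes: int = 2
    channels: str | Sequence[str] = "c3czc4_3"
    fs: float = 250.0
    duration: float = 4.0
    rhythm_freqs: tuple[float, ...] | None = None
    erd_channels: tuple[tuple[str, ...], ...] | None = None
    erd_depth: float = 1.0
    noise_exponent: float = 1.0
    snr: float = 1.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def resolved_channels(self) -> tuple[str, ...]:
        if isinstance(self.channels, str):
            return ChannelSubset.named(self.channels).channels
        return tuple(self.channels)

    def resolved_effects(self) -> list[tuple[float, tuple[str, ...]]]:
        chans = self.resolved_channels()
        freqs = self.rhythm_freqs
        targets = self.erd_channels
        effects = []
        for c in range(self.n_classes):
            f = freqs[c] if freqs is not None else _DEFAULT_EFFECTS[c % 4][0]
            t = targets[c] if targets is not None else _DEFAULT_EFFECTS[c % 4][1]
            missing = [ch for ch in t if ch not in chans]
            if missing:
                raise ValueError(
                    f"class {c}: effect channels {missing} not in montage {chans}"
                )
            effects.append((float(f), tuple(t)))
        return effects

    def validate(self) -> None:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        self.resolved_effects()


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
    fs: float, alpha: float,
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^alpha."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0  # remove DC so trials are zero-mean
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / np.maximum(rms, 1e-30)


def generate(spec: SyntheticSpec) -> EEGEpochSet:
    """Deterministically generate the labeled epoch set described by ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chans = spec.resolved_channels()
    effects = spec.resolved_effects()
    n_samples = int(round(spec.fs * spec.duration))
    n_total = spec.n_trials_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
    t = np.arange(n_samples) / spec.fs
    window = np.hanning(n_samples)
    # normalize the windowed sinusoid to unit RMS so snr is an amplitude ratio
    win_rms = np.sqrt(np.mean(window**2) / 2.0)

    data = _one_over_f_noise(
        rng, (n_total, len(chans)), n_samples, spec.fs, spec.noise_exponent
    )
    amp = spec.snr * spec.erd_depth
    # phases are drawn unconditionally so the background noise and trial
    # shuffle are identical across specs that differ only in effect size
    phases = rng.uniform(0, 2 * np.pi, size=n_total)
    if amp > 0:
        chan_index = {c: i for i, c in enumerate(chans)}
        for trial in range(n_total):
            freq, targets = effects[labels[trial]]
            osc = window * np.sin(2 * np.pi * freq * t + phases[trial])
            osc = amp * osc / win_rms
            for ch in targets:
                data[trial, chan_index[ch]] += osc
    order = rng.permutation(n_total)
    return EEGEpochSet(
        data=data[order],
        labels=labels[order],
        fs=spec.fs,
        channel_names=chans,
        t_start=0.0,
        meta={"synthetic": True, "seed": spec.seed, **spec.meta},
    )


def bandpower_baseline(
    epochs: EEGEpochSet,
    bands: Sequence[tuple[float, float]] = ((8.0, 12.0), (13.0, 30.0)),
    test_fraction: float = 0.25,
    seed: int = 0,
) -> float:
    """Accuracy of a log band-power + nearest-class-centroid rule.

    A deliberately simple reference decoder used to place the synthetic
    difficulty on a known scale: ~1.0 for cleanly separable specs, chance
    when the class effect is absent.
    """
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import NearestCentroid

    if epochs.n_classes < 2:
        raise ValueError("need at least 2 classes")
    freqs, psd = _signal.welch(epochs.data, fs=epochs.fs, nperseg=min(
        256, epochs.n_samples), axis=-1)
    feats = []
    for lo, hi in bands:
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band ({lo}, {hi}) Hz outside resolved spectrum")
        power = psd[:, :, sel].mean(axis=-1)
        if np.any(power <= 0):
            raise FloatingPointError("degenerate band power")
        feats.append(np.log(power))
    X = np.concatenate(feats, axis=1)
    y = epochs.labels
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    clf = NearestCentroid()
    clf.fit(X_tr, y_tr)
    return float((clf.predict(X_te) == y_te).mean())
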