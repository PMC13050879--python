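"""Segmentation-and-reconstruction (S&R) augmentation for epoched EEG.

Training trials of one class are cut into ``n_segments`` equal, ordered
temporal slots; new trials are assembled by drawing each slot from a random
same-class donor, keeping slot order intact so the within-trial rhythm
structure is preserved.  Bounded Gaussian noise is then added to the
reconstructed trials only, and the result is mixed and shuffled with the
originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import EEGEpochSet

logger = logging.getLogger(__name__)


class ProtocolError(RuntimeError):
    """Augmentation applied outside the training split."""


@dataclass
class AugmentConfig:
    """S&R settings.

    ``n_segments`` (Ns) must divide the trial length; with 1000-sample
    trials the default 8 gives 125-sample slots.  ``noise_sigma`` is the
    std of the injected Gaussian noise in normalized (post z-score) units;
    every noise value is clipped to ±``noise_bound``.  ``multiplier`` is
    the number of reconstructed trials generated per original trial.
    """

    n_segments: int = 8
    noise_sigma: float = 0.2
    noise_bound: float = 1.0
    multiplier: int = 1
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.n_segments < 1 or n_samples % self.n_segments != 0:
            raise ValueError(
                f"trial length {n_samples} not divisible by n_segments={self.n_segments}"
            )
        if self.multiplier < 0:
            raise ValueError("multiplier must be >= 0")
        if self.noise_bound <= 0:
            raise ValueError("noise_bound must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _check_not_test(epochs: EEGEpochSet) -> None:
    if epochs.meta.get("split") == "test":
        raise ProtocolError("augmentation must never touch the test split")


def segment_and_reconstruct(
    epochs: EEGEpochSet, cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> EEGEpochSet:
    """Generate ``multiplier`` recombined trials per original trial.

    Slot ``j`` of every new trial is slot ``j`` of a uniformly chosen
    same-class donor (with replacement, independently per slot).  A class
    with a single trial can only reproduce itself.
    """
    cfg.validate(epochs.n_samples)
    _check_not_test(epochs)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ns = cfg.n_segments
    seg_len = epochs.n_samples // ns
    new_data = []
    new_labels = []
    for cls in range(epochs.n_classes):
        cls_idx = np.flatnonzero(epochs.labels == cls)
        if cls_idx.size == 0:
            logger.warning("class %d has no trials; skipped by S&R", cls)
            continue
        # [n_cls, C, Ns, seg_len] view of this class's trials
        segs = epochs.data[cls_idx].reshape(
            cls_idx.size, epochs.n_channels, ns, seg_len
        )
        n_new = cls_idx.size * cfg.multiplier
        if n_new == 0:
            continue
        donors = rng.integers(0, cls_idx.size, size=(n_new, ns))
        # pick slot j from donor[t, j] for every new trial t
        rebuilt = segs[donors.T, :, np.arange(ns)[:, None]]  # [Ns, n_new, C, seg_len]
        rebuilt = rebuilt.transpose(1, 2, 0, 3).reshape(
            n_new, epochs.n_channels, epochs.n_samples
        )
        new_data.append(rebuilt)
        new_labels.append(np.full(n_new, cls, dtype=np.int64))
    if not new_data:
        data = np.empty((0,) + epochs.data.shape[1:])
        labels = np.empty(0, dtype=np.int64)
    else:
        data = np.concatenate(new_data)
        labels = np.concatenate(new_labels)
    out = epochs.with_data(data, labels=labels)
    out.meta["augmented"] = True
    return out


def add_bounded_noise(
    epochs: EEGEpochSet, cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> EEGEpochSet:
    """Add Normal(0, sigma^2) noise clipped to [-noise_bound, +noise_bound]."""
    if cfg.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if cfg.noise_sigma == 0 or epochs.n_trials == 0:
        return epochs.with_data(epochs.data.copy())
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, cfg.noise_sigma, size=epochs.data.shape)
    np.clip(noise, -cfg.noise_bound, cfg.noise_bound, out=noise)
    return epochs.with_data(epochs.data + noise)


def build_augmented_train_set(
    epochs: EEGEpochSet, cfg: AugmentConfig
) -> EEGEpochSet:
    """Original trials plus noised S&R reconstructions, shuffled together.

    Output size is ``n * (1 + multiplier)`` with every class count scaled
    by the same factor.  Fully determined by ``cfg.seed``.
    """
    cfg.validate(epochs.n_samples)
    _check_not_test(epochs)
    rng = np.random.default_rng(cfg.seed)
    recon = segment_and_reconstruct(epochs, cfg, rng=rng)
    recon = add_bounded_noise(recon, cfg, rng=rng)
    data = np.concatenate([epochs.data, recon.data])
    labels = np.concatenate([epochs.labels, recon.labels])
    order = rng.permutation(len(labels))
    out = epochs.with_data(data[order], labels=labels[order])
    out.meta["augmented"] = True
    return out
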