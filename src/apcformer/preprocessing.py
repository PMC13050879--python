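"""Band-pass filtering, epoch cropping, and per-trial z-score normalization.

The normalization is deliberately local: every (trial, channel) fragment is
standardized on its own mean and unbiased standard deviation, so baseline
drift in one trial or gain differences between channels never leak across
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EEGEpochSet


class ConfigurationError(ValueError):
    pass


class DegenerateChannelError(ValueError):
    """A (trial, channel) fragment has zero variance and cannot be z-scored."""


@dataclass
class PreprocConfig:
    """Settings for the filtering/cropping/normalization chain.

    ``band_low``/``band_high`` bound the retained frequency band in Hz
    (default 0.5-30 Hz, covering mu and beta sensorimotor rhythms).
    ``zero_phase`` applies the filter forward and backward so waveform
    latencies are preserved.
    """

    band_low: float = 0.5
    band_high: float = 30.0
    crop_start: float = 2.0
    crop_end: float = 6.0
    filter_order: int = 4
    zero_phase: bool = True
    zscore_epsilon: float = 0.0  # 0 -> hard error on constant fragments

    def validate(self, fs: float) -> None:
        if not 0 <= self.band_low < self.band_high:
            raise ConfigurationError(
                f"need 0 <= band_low < band_high, got [{self.band_low}, {self.band_high}]"
            )
        if self.band_high >= fs / 2:
            raise ConfigurationError(
                f"band_high={self.band_high} Hz must be below Nyquist {fs / 2} Hz"
            )
        if self.crop_end <= self.crop_start:
            raise ConfigurationError("crop_end must exceed crop_start")


def bandpass(epochs: EEGEpochSet, cfg: PreprocConfig) -> EEGEpochSet:
    """Butterworth band-pass along the time axis of every trial/channel.

    Zero-phase (forward-backward) by default; `sosfiltfilt` extends the
    epoch by odd reflection internally, limiting edge transients.
    """
    cfg.validate(epochs.fs)
    nyq = epochs.fs / 2
    if cfg.band_low <= 0:
        band = cfg.band_high / nyq
        btype = "lowpass"
    else:
        band = [cfg.band_low / nyq, cfg.band_high / nyq]
        btype = "bandpass"
    if cfg.zero_phase:
        # forward-backward with Gustafsson initial conditions: on short
        # epochs the slow-settling low cutoff makes pad-based filtfilt ring
        # through the whole trial, while 'gust' minimizes edge transients
        b, a = signal.butter(cfg.filter_order, band, btype=btype)
        filtered = signal.filtfilt(b, a, epochs.data, axis=-1, method="gust")
    else:
        sos = signal.butter(cfg.filter_order, band, btype=btype, output="sos")
        filtered = signal.sosfilt(sos, epochs.data, axis=-1)
    out = epochs.with_data(np.ascontiguousarray(filtered))
    out.meta["bandpass_hz"] = [cfg.band_low, cfg.band_high]
    return out


def crop_epoch(
    epochs: EEGEpochSet, crop_start: float, crop_end: float
) -> EEGEpochSet:
    """Crop every trial to the half-open window [crop_start, crop_end) seconds.

    Times are relative to the cue (same clock as ``t_start``); the result
    has ``round((crop_end - crop_start) * fs)`` samples.
    """
    if crop_end <= crop_start:
        raise ValueError("crop_end must exceed crop_start")
    t_end = epochs.t_start + epochs.n_samples / epochs.fs
    eps = 0.5 / epochs.fs
    if crop_start < epochs.t_start - eps or crop_end > t_end + eps:
        raise ValueError(
            f"crop window [{crop_start}, {crop_end}) s outside recorded epoch "
            f"[{epochs.t_start}, {t_end}) s"
        )
    i0 = int(round((crop_start - epochs.t_start) * epochs.fs))
    n_out = int(round((crop_end - crop_start) * epochs.fs))
    if i0 + n_out > epochs.n_samples:
        raise ValueError("crop window exceeds trial end")
    out = epochs.with_data(epochs.data[:, :, i0:i0 + n_out].copy(),
                           t_start=crop_start)
    return out


def zscore(epochs: EEGEpochSet, epsilon: float = 0.0) -> EEGEpochSet:
    """Standardize each (trial, channel) fragment to mean 0, unbiased std 1.

    The standard deviation uses the T-1 denominator to reduce the bias of
    the single-fragment estimate.  Statistics are never pooled across
    trials or channels.  A zero-variance fragment raises
    :class:`DegenerateChannelError` unless ``epsilon`` > 0, in which case
    ``epsilon`` is added to the denominator.
    """
    if epochs.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples per trial")
    x = epochs.data
    mu = x.mean(axis=-1, keepdims=True)
    sigma = x.std(axis=-1, ddof=1, keepdims=True)
    if epsilon <= 0:
        flat = np.argwhere(sigma[:, :, 0] == 0)
        if flat.size:
            trial, chan = flat[0]
            raise DegenerateChannelError(
                f"zero variance at trial {trial}, channel "
                f"{epochs.channel_names[chan]!r} (index {chan})"
            )
        denom = sigma
    else:
        denom = sigma + epsilon
    return epochs.with_data((x - mu) / denom, normalized=True)


def preprocess(epochs: EEGEpochSet, cfg: PreprocConfig) -> EEGEpochSet:
    """Full chain: band-pass -> crop to the imagery window -> z-score."""
    out = bandpass(epochs, cfg)
    out = crop_epoch(out, cfg.crop_start, cfg.crop_end)
    return zscore(out, epsilon=cfg.zscore_epsilon)
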