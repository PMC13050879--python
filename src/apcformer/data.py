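"""Epoched-EEG data model and canonical on-disk bundle.

The unit of data throughout the package is the :class:`EEGEpochSet`: a stack
of fixed-length, cue-locked multichannel EEG trials with integer class
labels.  Bundles are written as one raw little-endian binary file per array
field plus a JSON sidecar carrying dtype, shape and metadata, so they can be
read from any language without a special library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

FORMAT_VERSION = 1

#: 10-20 montage of the 22-electrode motor-imagery cap, in recording order.
MONTAGE_22 = [
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
]

# Hierarchical channel expansion: each subset strictly extends the previous,
# growing outward from the central electrodes C3/Cz/C4.
_SUBSET_ORDER = ["c3czc4_3", "central_9", "central_13", "central_17", "all_22"]
_SUBSET_CHANNELS = {
    "c3czc4_3": ["C3", "Cz", "C4"],
    "central_9": ["C3", "Cz", "C4", "Fz", "Pz", "C1", "C2", "FCz", "CPz"],
    "central_13": ["C3", "Cz", "C4", "Fz", "Pz", "C1", "C2", "FCz", "CPz",
                   "FC1", "FC2", "CP1", "CP2"],
    "central_17": ["C3", "Cz", "C4", "Fz", "Pz", "C1", "C2", "FCz", "CPz",
                   "FC1", "FC2", "CP1", "CP2", "FC3", "FC4", "CP3", "CP4"],
    "all_22": list(MONTAGE_22),
}


class FormatError(ValueError):
    """A bundle on disk does not match its declared layout."""


@dataclass(frozen=True)
class ChannelSubset:
    """A named, ordered electrode subset of the 22-channel montage."""

    name: str
    channels: tuple[str, ...]

    @classmethod
    def named(cls, name: str) -> "ChannelSubset":
        if name not in _SUBSET_CHANNELS:
            raise KeyError(
                f"unknown channel subset {name!r}; choose from {_SUBSET_ORDER}"
            )
        return cls(name, tuple(_SUBSET_CHANNELS[name]))

    @staticmethod
    def hierarchy() -> list["ChannelSubset"]:
        """The five nested subsets, smallest first."""
        return [ChannelSubset.named(n) for n in _SUBSET_ORDER]


@dataclass
class EEGEpochSet:
    """Labeled trial tensor ``[n_trials, n_channels, n_samples]``.

    ``data`` is in microvolts as recorded, or unit-variance values after
    z-scoring (``normalized`` is then set).  ``t_start`` is the epoch start
    in seconds relative to the task cue; epoch windows are half-open.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    t_start: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise FormatError(
                f"data must be [trial, channel, time], got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("data contains non-finite values")
        if self.labels.ndim != 1 or len(self.labels) != self.n_trials:
            raise FormatError(
                f"labels: expected {self.n_trials} entries, got shape {self.labels.shape}"
            )
        if len(self.channel_names) != self.n_channels:
            raise FormatError(
                f"channel_names: {len(self.channel_names)} names for "
                f"{self.n_channels} channels"
            )
        if not self.fs > 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if self.n_trials and self.labels.min() < 0:
            raise FormatError("labels must be non-negative class indices")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_trials else 0

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray, **kwargs: Any) -> "EEGEpochSet":
        """Copy of this set with new data and otherwise shared metadata."""
        out = replace(self, data=data, meta=dict(self.meta), **kwargs)
        return out

    def subset_trials(self, index: np.ndarray) -> "EEGEpochSet":
        index = np.asarray(index)
        return replace(
            self, data=self.data[index], labels=self.labels[index],
            meta=dict(self.meta),
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGEpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channel_names == other.channel_names
            and self.t_start == other.t_start
            and self.meta == other.meta
            and self.normalized == other.normalized
        )


# -- canonical bundle ----------------------------------------------------

def save_bundle(epochs: EEGEpochSet, path: str | Path) -> Path:
    """Write ``epochs`` to a bundle directory: data.bin + labels.bin + meta.json."""
    epochs.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {"data": epochs.data, "labels": epochs.labels}
    sidecar: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "fs": epochs.fs,
        "channel_names": list(epochs.channel_names),
        "t_start": epochs.t_start,
        "normalized": epochs.normalized,
        "meta": epochs.meta,
        "arrays": {},
    }
    for name, arr in arrays.items():
        fname = f"{name}.bin"
        arr.astype(arr.dtype.newbyteorder("<")).tofile(path / fname)
        sidecar["arrays"][name] = {
            "file": fname,
            "dtype": arr.dtype.newbyteorder("<").str,
            "shape": list(arr.shape),
            "order": "C",
        }
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_bundle(path: str | Path) -> EEGEpochSet:
    """Load a bundle written by :func:`save_bundle`, validating invariants."""
    path = Path(path)
    sidecar_path = path / "meta.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar meta.json in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("format_version") != FORMAT_VERSION:
        raise FormatError(
            f"unsupported format_version {sidecar.get('format_version')!r}"
        )
    arrays: dict[str, np.ndarray] = {}
    for name in ("data", "labels"):
        if name not in sidecar.get("arrays", {}):
            raise FormatError(f"sidecar missing array entry {name!r}")
        entry = sidecar["arrays"][name]
        raw = np.fromfile(path / entry["file"], dtype=np.dtype(entry["dtype"]))
        expected = int(np.prod(entry["shape"])) if entry["shape"] else 1
        if raw.size != expected:
            raise FormatError(
                f"array {name!r}: file holds {raw.size} values, sidecar "
                f"declares shape {entry['shape']} ({expected} values)"
            )
        arrays[name] = raw.reshape(entry["shape"])
    if arrays["data"].ndim == 3 and len(sidecar["channel_names"]) != arrays["data"].shape[1]:
        raise FormatError(
            f"channel_names: sidecar lists {len(sidecar['channel_names'])} "
            f"names but data has {arrays['data'].shape[1]} channels"
        )
    return EEGEpochSet(
        data=arrays["data"],
        labels=arrays["labels"],
        fs=sidecar["fs"],
        channel_names=tuple(sidecar["channel_names"]),
        t_start=sidecar["t_start"],
        meta=dict(sidecar.get("meta", {})),
        normalized=bool(sidecar.get("normalized", False)),
    )


def select_channels(
    epochs: EEGEpochSet, subset: ChannelSubset | str | Sequence[str]
) -> EEGEpochSet:
    """Slice and reorder channels to follow ``subset``'s definition."""
    if isinstance(subset, str):
        subset = ChannelSubset.named(subset)
    names = subset.channels if isinstance(subset, ChannelSubset) else tuple(subset)
    lookup = {name: i for i, name in enumerate(epochs.channel_names)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    idx = np.array([lookup[n] for n in names], dtype=np.intp)
    return replace(
        epochs, data=epochs.data[:, idx, :], channel_names=names,
        meta=dict(epochs.meta),
    )


def import_raw_epochs(
    path: str | Path,
    tmin: float,
    tmax: float,
    event_id: Mapping[str, int] | None = None,
) -> EEGEpochSet:
    """Import epochs from an EDF/GDF recording (optional; requires ``mne``).

    Events are taken from the file's annotations; ``tmin``/``tmax`` are in
    seconds relative to each cue.  The test suite does not rely on this.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF/GDF import requires the optional 'mne' extra") from exc
    path = Path(path)
    if path.suffix.lower() == ".gdf":  # pragma: no cover - format-dependent
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    events, found_ids = mne.events_from_annotations(raw, event_id=event_id,
                                                   verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)
    ep = mne.Epochs(raw, events, event_id=found_ids, tmin=tmin,
                    tmax=tmax, baseline=None, preload=True, picks=picks,
                    verbose="error")
    codes = sorted(found_ids.values())
    remap = {c: i for i, c in enumerate(codes)}
    labels = np.array([remap[e] for e in ep.events[:, 2]])
    return EEGEpochSet(
        data=ep.get_data() * 1e6,  # MNE volts -> microvolts
        labels=labels,
        fs=float(ep.info["sfreq"]),
        channel_names=tuple(ep.ch_names),
        t_start=tmin,
        meta={"source": str(path)},
    )
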