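"""Shared fixtures: small deterministic epoch sets and model configs."""

from __future__ import annotations

import numpy as np
import pytest

from apcformer.data import EEGEpochSet
from apcformer.model import ModelConfig
from apcformer.sat import SATConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng) -> EEGEpochSet:
    """8 trials x 3 channels x 200 samples at 250 Hz, 2 balanced classes."""
    data = rng.standard_normal((8, 3, 200))
    labels = np.array([0, 1] * 4)
    return EEGEpochSet(
        data=data, labels=labels, fs=250.0,
        channel_names=("C3", "Cz", "C4"), t_start=0.0,
        meta={"split": "train"},
    )


@pytest.fixture
def montage22_epochs(rng) -> EEGEpochSet:
    """12 trials on the full 22-channel montage, 4 classes."""
    from apcformer.data import MONTAGE_22

    data = rng.standard_normal((12, 22, 250))
    labels = np.array([0, 1, 2, 3] * 3)
    return EEGEpochSet(data=data, labels=labels, fs=250.0,
                       channel_names=tuple(MONTAGE_22))


@pytest.fixture
def tiny_model_config() -> ModelConfig:
    """A scaled-down decoder that still exercises every stage."""
    return ModelConfig(
        C=3, T=200, fs=250.0, n_classes=2,
        F1=4, F2=8, pool1=25, pool2=3, dropout=0.0,
        sat=SATConfig(d_model=8, n_heads=2, n_layers=1, window=3, stride=1,
                      dropout=0.0),
    )
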