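"""The motor-imagery EEG decoder: multi-scale convolutional front end,
cross-branch recalibration, position-aware enhancement, sparse-attention
encoder and softmax classifier.

Stage shapes for the reference four-class configuration (C=22 channels,
T=1000 samples at 250 Hz):

    input  (B, 1, 22, 1000)
    STConv -> three branches, each (B, 32, 1, 13)    # pool 75, floor
    AFR    -> same shapes, recalibrated
    fusion -> (B, 32, 1, 39) -> PAE -> tokens (B, 13, 32)
    SAT    -> (B, 13, 32)
    head   -> class probabilities (B, 4)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, concatenate, softmax, where_const
from .sat import SATConfig, SATEncoder


def _nearest_odd(x: float) -> int:
    return 2 * int(x // 2) + 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The three temporal kernels default to fs/2, fs/4 and fs/8 samples,
    rounded to the nearest odd length so 'same' padding is symmetric
    (125/63/31 at 250 Hz).  ``spatial_conv_mode`` selects depthwise
    (default, EEGNet-style, multiplier F2/F1) or standard spatial
    convolution; ``classifier_hidden=None`` uses a single dense layer.
    """

    C: int = 22
    T: int = 1000
    fs: float = 250.0
    n_classes: int = 4
    F1: int = 16
    F2: int = 32
    temporal_kernels: tuple[int, int, int] | None = None
    pool1: int = 75
    pae_kernels: tuple[int, int] = (3, 7)
    pool2: int = 3
    dropout: float = 0.3
    cbam_reduction: int = 8
    classifier_hidden: int | None = None
    spatial_conv_mode: str = "depthwise"
    sat: SATConfig = field(default_factory=SATConfig)

    def __post_init__(self) -> None:
        if self.temporal_kernels is None:
            self.temporal_kernels = tuple(
                _nearest_odd(self.fs / div) for div in (2, 4, 8)
            )
        self.validate()

    def validate(self) -> None:
        if self.T < self.pool1:
            raise ValueError(f"T={self.T} shorter than pool1={self.pool1}")
        if self.spatial_conv_mode not in ("depthwise", "standard"):
            raise ValueError(
                f"unknown spatial_conv_mode {self.spatial_conv_mode!r}"
            )
        if self.spatial_conv_mode == "depthwise" and self.F2 % self.F1:
            raise ValueError("depthwise spatial conv needs F2 divisible by F1")
        if self.F2 != self.sat.d_model:
            raise ValueError(
                f"F2={self.F2} must equal sat.d_model={self.sat.d_model}"
            )
        if 3 * self.token_length() < self.pool2:
            raise ValueError("fused sequence shorter than pool2")
        self.sat.validate()

    def token_length(self) -> int:
        """Token count entering the attention encoder (= floor(T/pool1);
        the threefold concatenation and pool2=3 restore the same length)."""
        return self.T // self.pool1

    def fused_token_length(self) -> int:
        return (3 * self.token_length()) // self.pool2


class STConvBranch(nn.Module):
    """One temporal scale: temporal conv -> spatial conv collapsing the
    channel axis -> batch norm -> ELU -> average pool -> dropout."""

    def __init__(self, cfg: ModelConfig, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.temporal = nn.Conv2d(1, cfg.F1, (1, kernel), rng, padding="same")
        if cfg.spatial_conv_mode == "depthwise":
            self.spatial = nn.Conv2d(cfg.F1, cfg.F2, (cfg.C, 1), rng,
                                     groups=cfg.F1)
        else:
            self.spatial = nn.Conv2d(cfg.F1, cfg.F2, (cfg.C, 1), rng)
        self.bn = nn.BatchNorm2d(cfg.F2)
        self.pool = nn.AvgPool2d((1, cfg.pool1))
        self.drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        y = self.spatial(self.temporal(x))
        y = self.bn(y).elu()
        return self.drop(self.pool(y))


class CBAM(nn.Module):
    """Convolutional block attention: channel gate then spatial gate.

    Channel path: global max/average pooling -> shared two-layer MLP
    (reduction r) -> summed -> sigmoid.  Spatial path: channel-wise
    max/mean maps -> 3x3 conv -> sigmoid.  Both gates multiply the input,
    so all weights lie strictly in (0, 1).
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.mlp_in = nn.Linear(channels, hidden, rng)
        self.mlp_out = nn.Linear(hidden, channels, rng)
        self.spatial_conv = nn.Conv2d(2, 1, (3, 3), rng, padding="same")

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[0], x.shape[1]
        flat = x.reshape(B, C, -1)
        mx = flat.max(axis=2)
        av = flat.mean(axis=2)
        gate = (self._mlp(mx) + self._mlp(av)).sigmoid()
        x = x * gate.reshape(B, C, 1, 1)

        ch_max = x.max(axis=1, keepdims=True)
        ch_mean = x.mean(axis=1, keepdims=True)
        smap = concatenate([ch_max, ch_mean], axis=1)
        sgate = self.spatial_conv(smap).sigmoid()
        return x * sgate

    def _mlp(self, v: Tensor) -> Tensor:
        return self.mlp_out(self.mlp_in(v).elu())


class AFR(nn.Module):
    """Adaptive feature recalibration: each branch keeps its own features
    and receives the sum of the other branches' features, then is
    recalibrated by an independent CBAM."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cbams = [
            CBAM(cfg.F2, cfg.cbam_reduction, rng) for _ in range(3)
        ]

    @staticmethod
    def interact(branches: list[Tensor]) -> list[Tensor]:
        total = branches[0] + branches[1] + branches[2]
        # out_i = b_i + sum_{j != i} b_j, i.e. the full cross-branch sum
        return [total, total, total]

    def forward(self, branches: list[Tensor]) -> list[Tensor]:
        shapes = {tuple(b.shape) for b in branches}
        if len(branches) != 3 or len(shapes) != 1:
            raise ValueError("AFR expects three same-shape branches")
        mixed = self.interact(branches)
        return [cbam(b) for cbam, b in zip(self.cbams, mixed)]


class PAE(nn.Module):
    """Position-aware enhancement: parallel (1,3)/(1,7) convolutions with
    batch norm, summed and activated, pooled to the token length, then a
    learnable positional matrix (standard-normal initialized, trained by
    backpropagation) is added elementwise."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        k1, k2 = cfg.pae_kernels
        self.conv_a = nn.Conv2d(cfg.F2, cfg.F2, (1, k1), rng, padding="same")
        self.conv_b = nn.Conv2d(cfg.F2, cfg.F2, (1, k2), rng, padding="same")
        self.bn_a = nn.BatchNorm2d(cfg.F2)
        self.bn_b = nn.BatchNorm2d(cfg.F2)
        self.pool = nn.AvgPool2d((1, cfg.pool2))
        self.drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            rng.integers(2**31)))
        self.positional = nn.Parameter(
            rng.standard_normal((cfg.fused_token_length(), cfg.F2))
        )

    def forward(self, fused: Tensor) -> Tensor:
        y = (self.bn_a(self.conv_a(fused)) + self.bn_b(self.conv_b(fused))).elu()
        y = self.drop(self.pool(y))
        B, F2 = y.shape[0], y.shape[1]
        tokens = y.reshape(B, F2, -1).transpose(0, 2, 1)   # [B, L, F2]
        return tokens + self.positional


class Classifier(nn.Module):
    """Flatten -> (optional hidden dense with dropout) -> dense -> softmax."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        in_dim = cfg.fused_token_length() * cfg.F2
        if cfg.classifier_hidden:
            self.hidden = nn.Linear(in_dim, cfg.classifier_hidden, rng)
            self.drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
                rng.integers(2**31)))
            self.out = nn.Linear(cfg.classifier_hidden, cfg.n_classes, rng)
        else:
            self.hidden = None
            self.out = nn.Linear(in_dim, cfg.n_classes, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        B = tokens.shape[0]
        x = tokens.reshape(B, -1)
        if self.hidden is not None:
            x = self.drop(self.hidden(x).elu())
        return softmax(self.out(x), axis=-1)


class APCformer(nn.Module):
    """End-to-end decoder; input [batch, 1, C, T], output class probabilities."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branches = [
            STConvBranch(cfg, k, rng) for k in cfg.temporal_kernels
        ]
        self.afr = AFR(cfg, rng)
        self.pae = PAE(cfg, rng)
        self.sat = SATEncoder(cfg.sat, rng)
        self.head = Classifier(cfg, rng)

    def stconv(self, x: Tensor) -> list[Tensor]:
        return [branch(x) for branch in self.branches]

    def tokens(self, x: Tensor) -> Tensor:
        """Everything before the classifier: the encoded token sequence."""
        branches = self.afr(self.stconv(x))
        fused = concatenate(branches, axis=3)
        return self.sat(self.pae(fused))

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = nn.as_tensor(np.asarray(x.data if isinstance(x, Tensor) else x,
                                    dtype=np.float32))
        if x.ndim != 4 or x.shape[2] != self.cfg.C or x.shape[3] != self.cfg.T:
            raise ValueError(
                f"expected input [B, 1, {self.cfg.C}, {self.cfg.T}], "
                f"got {tuple(x.shape)}"
            )
        return self.head(self.tokens(x))

    def predict(self, data: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class predictions for epoched data [n, C, T] (eval mode)."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(data), batch_size):
            probs = self.forward(data[i:i + batch_size, None, :, :])
            out.append(np.argmax(probs.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def cross_entropy_loss(probs: Tensor, labels: np.ndarray,
                       eps: float = 1e-12) -> Tensor:
    """Mean over the batch of -log p(true class); probabilities are clamped
    at ``eps`` so a confident wrong prediction cannot produce -inf."""
    labels = np.asarray(labels)
    batch = probs.shape[0]
    picked = probs[np.arange(batch), labels]
    clamped = where_const(picked.data > eps, picked, eps)
    return -(clamped.log().mean())


def count_parameters(model: APCformer) -> tuple[int, dict[str, int]]:
    """Total learnable parameter count and a per-component breakdown."""
    breakdown: dict[str, int] = {}
    for name, p in model.named_parameters():
        component = name.split(".")[0]
        breakdown[component] = breakdown.get(component, 0) + p.size
    return sum(breakdown.values()), breakdown


# -- checkpoints ---------------------------------------------------------

CHECKPOINT_VERSION = 1


def _config_to_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    d["sat"] = asdict(cfg.sat)
    return d


def config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    sat = d.pop("sat", {})
    d["temporal_kernels"] = (tuple(d["temporal_kernels"])
                             if d.get("temporal_kernels") else None)
    d["pae_kernels"] = tuple(d.get("pae_kernels", (3, 7)))
    return ModelConfig(sat=SATConfig(**sat), **d)


def save_checkpoint(model: APCformer, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "config": _config_to_dict(model.cfg),
    }
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> APCformer:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta.get("checkpoint_version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = APCformer(config_from_dict(meta["config"]))
    model.load_state_dict(state)
    return model.eval()
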