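"""Sparse Information Aggregation Transformer (SAT).

The token sequence is cut into ``m`` sliding-window blocks of ``s`` tokens
every ``d`` positions.  Two attention paths are combined per head:

* **aggregation attention** — each query attends to the ``m`` block-mean
  keys/values, giving a coarse global summary at O(n·m) cost instead of
  O(n²);
* **top attention** — per query, the ``k`` blocks with the largest
  aggregation scores are re-expanded to their original ``k·s`` tokens and
  attended at full resolution, recovering fine-grained local structure at
  O(n·k·s) cost.

The block scores of the first path are reused for the top-k selection, so
the sparsification itself costs nothing extra.  The functional NumPy API
below mirrors the individual steps for analysis and testing; the
:class:`SATEncoder` is the trainable autograd version used by the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, gather_tokens, index_select, softmax


# ---------------------------------------------------------------------------
# block partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockPartition:
    """Sliding-window block structure over an ``n``-token sequence.

    Block ``j`` (0-based) covers token indices ``j*d .. j*d + s - 1``;
    ``m = floor((n - s) / d) + 1`` blocks in total.  With ``d >= s`` the
    blocks tile the sequence disjointly, with ``d < s`` they overlap and
    tokens are listed in several blocks (``n_s = m * s >= n``).
    """

    n: int
    s: int
    d: int
    index_map: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return self.index_map.shape[0]

    @property
    def n_s(self) -> int:
        return self.index_map.size

    def permuted(self, order: np.ndarray) -> "BlockPartition":
        """The same partition with blocks listed in a different order."""
        order = np.asarray(order)
        if sorted(order.tolist()) != list(range(self.m)):
            raise ValueError("order must be a permutation of the blocks")
        return BlockPartition(self.n, self.s, self.d, self.index_map[order])


def partition_sliding_window(n: int, s: int, d: int) -> BlockPartition:
    """Partition an ``n``-token sequence into sliding windows."""
    if not 1 <= s <= n:
        raise ValueError(f"window s={s} must satisfy 1 <= s <= n={n}")
    if d < 1:
        raise ValueError(f"stride d={d} must be >= 1")
    m = (n - s) // d + 1
    starts = np.arange(m) * d
    index_map = starts[:, None] + np.arange(s)[None, :]
    return BlockPartition(n=n, s=s, d=d, index_map=index_map)


# ---------------------------------------------------------------------------
# functional (NumPy) attention steps
# ---------------------------------------------------------------------------

def aggregate_block_kv(
    K: np.ndarray, V: np.ndarray, part: BlockPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic block means of keys and values: rows ``j`` of the outputs
    are the means of ``K``/``V`` over block ``j``'s token indices."""
    K = np.asarray(K)
    V = np.asarray(V)
    if K.shape[0] != part.n or V.shape[0] != part.n:
        raise ValueError(
            f"K/V must have {part.n} rows, got {K.shape[0]}/{V.shape[0]}"
        )
    K_avg = K[part.index_map].mean(axis=1)
    V_avg = V[part.index_map].mean(axis=1)
    return K_avg, V_avg


def aggregation_attention(
    Q: np.ndarray, K_avg: np.ndarray, V_avg: np.ndarray, d_k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax attention of every query over the block-mean keys/values.

    Returns ``(output, S_m)`` where ``S_m`` is the pre-softmax score matrix
    ``Q K_avg^T / sqrt(d_k)`` of shape [n, m], kept for reuse by the top-k
    selection.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    S_m = (Q @ K_avg.T) / np.sqrt(d_k)
    w = _softmax_np(S_m)
    return w @ V_avg, S_m


def topk_block_mask(S_m: np.ndarray, k: int) -> np.ndarray:
    """Additive mask keeping, per query row, exactly the ``k`` best blocks.

    Selected entries are 0, the rest ``-inf``.  Ties at the k-th score go
    to the lowest block index (stable selection), so the mask is
    deterministic.
    """
    S_m = np.asarray(S_m)
    m = S_m.shape[-1]
    if not 1 <= k <= m:
        raise ValueError(f"k={k} must satisfy 1 <= k <= m={m}")
    order = np.argsort(-S_m, axis=-1, kind="stable")
    sel = order[..., :k]
    mask = np.full(S_m.shape, -np.inf)
    np.put_along_axis(mask, sel, 0.0, axis=-1)
    return mask


def top_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray,
    part: BlockPartition, mask: np.ndarray, d_k: int,
) -> np.ndarray:
    """Full-resolution attention over the restored tokens of selected blocks.

    For each query, the original ``s`` tokens of its masked-in blocks are
    recovered (duplicates kept when windows overlap) and attended with a
    fresh softmax over those ``k*s`` tokens only.
    """
    Q = np.asarray(Q)
    n, m = mask.shape
    selected = mask == 0
    counts = selected.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("every query row must select at least one block")
    if not np.all(counts == counts[0]):
        raise ValueError("mask must select the same number of blocks per row")
    k = int(counts[0])
    # [n, k] block ids per query, ascending
    block_ids = np.nonzero(selected)[1].reshape(n, k)
    token_idx = part.index_map[block_ids].reshape(n, k * part.s)
    K_sel = K[token_idx]                     # [n, k*s, d_k]
    V_sel = V[token_idx]
    logits = np.einsum("nd,ntd->nt", Q, K_sel) / np.sqrt(d_k)
    w = _softmax_np(logits)
    return np.einsum("nt,ntd->nd", w, V_sel)


def _softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def resolve_top_k(top_k: int | str, m: int) -> int:
    """The blocks kept per query; ``"auto"`` keeps floor(m/3), at least 1,
    staying below half of the block count as sparsity requires."""
    if top_k == "auto":
        return max(1, m // 3)
    k = int(top_k)
    if not 1 <= k <= m:
        raise ValueError(f"top_k={k} out of range for m={m} blocks")
    return k


# ---------------------------------------------------------------------------
# trainable encoder
# ---------------------------------------------------------------------------

@dataclass
class SATConfig:
    """Encoder hyperparameters.

    ``d_model`` equals the feature width F2 handed over by the front end.
    ``window``/``stride`` define the block partition (defaults are the
    four-class optimum s=4, d=1); ``top_k="auto"`` keeps floor(m/3) blocks.
    ``ffn_expansion=0`` omits the feed-forward sublayer entirely (the
    default architecture); > 0 inserts one with that width multiplier.
    """

    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 6
    window: int = 4
    stride: int = 1
    top_k: int | str = "auto"
    ffn_expansion: float = 0.0
    dropout: float = 0.3

    def validate(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")


class SparseMultiheadAttention(nn.Module):
    """Multi-head combination of aggregation and top attention.

    Per head, the aggregation output and the top-attention output are
    summed elementwise before head concatenation and output projection.
    The top-k selection reuses the aggregation score matrix and is treated
    as a discrete (non-differentiated) choice; gradients flow through the
    scores, keys and values of the selected tokens.
    """

    def __init__(self, cfg: SATConfig, rng: np.random.Generator):
        super().__init__()
        dm = cfg.d_model
        self.wq = nn.Linear(dm, dm, rng)
        self.wk = nn.Linear(dm, dm, rng)
        self.wv = nn.Linear(dm, dm, rng)
        self.wo = nn.Linear(dm, dm, rng)
        self.n_heads = cfg.n_heads
        self.top_k = cfg.top_k

    def forward(self, x: Tensor, part: BlockPartition) -> Tensor:
        B, n, dm = x.shape
        h = self.n_heads
        dh = dm // h
        k = resolve_top_k(self.top_k, part.m)

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, n, h, dh).transpose(0, 2, 1, 3)

        Q = split(self.wq(x))
        K = split(self.wk(x))
        V = split(self.wv(x))

        flat = part.index_map.reshape(-1)
        K_avg = index_select(K, flat, axis=2).reshape(
            B, h, part.m, part.s, dh).mean(axis=3)
        V_avg = index_select(V, flat, axis=2).reshape(
            B, h, part.m, part.s, dh).mean(axis=3)

        scale = float(1.0 / np.sqrt(dh))
        S_m = (Q @ K_avg.swapaxes(-1, -2)) * scale          # [B,h,n,m]
        agg = softmax(S_m, axis=-1) @ V_avg                  # [B,h,n,dh]

        # top-k block selection per query, reusing S_m (stable tie-break)
        order = np.argsort(-S_m.data, axis=-1, kind="stable")
        sel = np.sort(order[..., :k], axis=-1)               # [B,h,n,k]
        token_idx = part.index_map[sel].reshape(B, h, n * k * part.s)
        ks = k * part.s
        K_sel = gather_tokens(K, token_idx).reshape(B, h, n, ks, dh)
        V_sel = gather_tokens(V, token_idx).reshape(B, h, n, ks, dh)
        logits = (Q.reshape(B, h, n, 1, dh) * K_sel).sum(axis=-1) * scale
        w = softmax(logits, axis=-1)                         # [B,h,n,ks]
        top = (w.reshape(B, h, n, ks, 1) * V_sel).sum(axis=3)

        combined = agg + top
        merged = combined.transpose(0, 2, 1, 3).reshape(B, n, dm)
        return self.wo(merged)


class SATLayer(nn.Module):
    """Pre-norm encoder layer: x + MHA(LN(x)), optionally x + FFN(LN(x))."""

    def __init__(self, cfg: SATConfig, rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(cfg.d_model)
        self.attn = SparseMultiheadAttention(cfg, rng)
        self.drop1 = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            rng.integers(2**31)))
        if cfg.ffn_expansion > 0:
            hidden = max(1, int(round(cfg.d_model * cfg.ffn_expansion)))
            self.norm2 = nn.LayerNorm(cfg.d_model)
            self.ffn_in = nn.Linear(cfg.d_model, hidden, rng)
            self.ffn_out = nn.Linear(hidden, cfg.d_model, rng)
            self.drop2 = nn.Dropout(cfg.dropout, rng=np.random.default_rng(
                rng.integers(2**31)))
        else:
            self.norm2 = None

    def forward(self, x: Tensor, part: BlockPartition) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x), part))
        if self.norm2 is not None:
            y = self.ffn_out(self.ffn_in(self.norm2(x)).elu())
            x = x + self.drop2(y)
        return x


class SATEncoder(nn.Module):
    """Stack of ``n_layers`` sparse-attention layers (identity when 0)."""

    def __init__(self, cfg: SATConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.layers = [SATLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[1]
        if self.cfg.n_layers == 0:
            return x
        if n < self.cfg.window:
            raise ValueError(
                f"sequence length {n} shorter than window {self.cfg.window}"
            )
        part = partition_sliding_window(n, self.cfg.window, self.cfg.stride)
        for layer in self.layers:
            x = layer(x, part)
        return x
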