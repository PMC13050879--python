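"""The sparse attention mechanism, step by step on a toy sequence.

Shows the sliding-window partition, block-mean aggregation attention, the
top-k block selection that reuses the aggregation scores, and the restored
full-resolution top attention -- and that with singleton blocks the whole
construction collapses to ordinary dense attention.
"""

import numpy as np

from apcformer import (
    aggregate_block_kv,
    aggregation_attention,
    partition_sliding_window,
    top_attention,
    topk_block_mask,
)

rng = np.random.default_rng(0)
n, s, d, d_k = 13, 4, 1, 8
Q, K, V = rng.standard_normal((3, n, d_k))

part = partition_sliding_window(n, s, d)
print(f"{n} tokens, window {s}, stride {d} -> m = {part.m} blocks "
      f"({part.n_s} listed tokens, overlap since d < s)")

K_avg, V_avg = aggregate_block_kv(K, V, part)
agg_out, S_m = aggregation_attention(Q, K_avg, V_avg, d_k)
print(f"aggregation path: score matrix {S_m.shape} (n x m, not n x n)")

k = max(1, part.m // 3)
mask = topk_block_mask(S_m, k)
top_out = top_attention(Q, K, V, part, mask, d_k)
print(f"top path: {k} blocks/query kept -> attention over {k * s} restored "
      f"tokens per query")
print(f"combined output shape: {(agg_out + top_out).shape}")

# limit case: singleton blocks reproduce dense attention exactly
part1 = partition_sliding_window(n, 1, 1)
K1, V1 = aggregate_block_kv(K, V, part1)
out1, _ = aggregation_attention(Q, K1, V1, d_k)
logits = Q @ K.T / np.sqrt(d_k)
w = np.exp(logits - logits.max(-1, keepdims=True))
dense = (w / w.sum(-1, keepdims=True)) @ V
print(f"singleton-block vs dense attention max deviation: "
      f"{np.abs(out1 - dense).max():.2e} (identical up to rounding)")
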