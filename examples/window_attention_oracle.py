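"""Window attention against a hand-rolled dense softmax.

Builds random per-head Q/K/V and a relative-position bias table for a 7x7
window, runs the package's windowed attention, and compares it with a
plain numpy softmax(QK^T/sqrt(d) + B)V.  Agreement to ~1e-15 shows the
windowing machinery adds nothing beyond restricting the attention span.
"""

import numpy as np

from onet.swin import (AttentionInputs, build_relative_position_index,
                       window_attention)

m, heads, d = 7, 3, 5
rng = np.random.default_rng(0)
q, k, v = (rng.normal(size=(1, heads, m * m, d)) for _ in range(3))
table = rng.normal(size=((2 * m - 1) ** 2, heads))
ri = build_relative_position_index(m)

got = window_attention(AttentionInputs(q, k, v, table, ri, heads, d)).data[0]

worst = 0.0
for h in range(heads):
    logits = q[0, h] @ k[0, h].T / np.sqrt(d) + table[ri, h]
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    dense = (e / e.sum(axis=1, keepdims=True)) @ v[0, h]
    worst = max(worst, np.abs(got[:, h * d:(h + 1) * d] - dense).max())

print(f"window size {m} ({m * m} tokens), {heads} heads, head dim {d}")
print(f"bias table entries: {(2 * m - 1) ** 2} "
      f"(relative displacements in [-{m - 1}, {m - 1}] per axis)")
print(f"max |windowed - dense oracle| = {worst:.2e}")
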