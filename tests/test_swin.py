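"""Window partitioning, relative-position attention, shift masks and the
patch embed/merge/expand algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from onet import nn, swin
from onet.swin import (AttentionInputs, FinalExpandX4, PatchEmbed, PatchExpand,
                       PatchMerging, SwinBlock, TokenGrid, WindowSet,
                       build_relative_position_index, build_shift_mask,
                       cyclic_shift, partition_windows, reverse_windows,
                       window_attention)


def numbered_grid(h, w, c=1):
    return TokenGrid(np.arange(h * w * c, dtype=float).reshape(1, h * w, c), h, w)


def dense_window_attention_oracle(q, k, v, bias, mask=None):
    """Independent single-window attention: plain softmax loops, no engine."""
    d = q.shape[-1]
    logits = q @ k.T / np.sqrt(d) + bias
    if mask is not None:
        logits = logits + mask
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    return p @ v


# -- partition / reverse ------------------------------------------------------

def test_partition_counts_and_contents():
    ws = partition_windows(numbered_grid(4, 4), 2)
    assert ws.windows.shape == (4, 4, 1)
    # single-window identity case
    g = numbered_grid(3, 3)
    ws1 = partition_windows(g, 3)
    assert ws1.windows.shape == (1, 9, 1)
    np.testing.assert_array_equal(ws1.windows.data[0], g.tokens.data[0])
    # 6x6 numbered grid: window 0 holds tokens {0, 1, 6, 7}
    ws6 = partition_windows(numbered_grid(6, 6), 2)
    assert ws6.windows.data[0, :, 0].tolist() == [0, 1, 6, 7]


def test_partition_errors_name_dimensions():
    with pytest.raises(ValueError, match=r"5x6.*3"):
        partition_windows(numbered_grid(5, 6), 3)


@settings(derandomize=True, max_examples=25)
@given(hw=st.sampled_from([(4, 4), (8, 8), (6, 6), (4, 8), (12, 8)]),
       m=st.sampled_from([1, 2, 4]))
def test_partition_reverse_round_trip_bit_exact(hw, m):
    h, w = hw
    if h % m or w % m:
        m = 2 if h % 2 == 0 else 1
    rng = np.random.default_rng(h * 100 + w * 10 + m)
    tokens = rng.normal(size=(2, h * w, 3))
    g = TokenGrid(nn.Tensor(tokens), h, w)
    back = reverse_windows(partition_windows(g, m))
    np.testing.assert_array_equal(back.tokens.data, tokens)


def test_reverse_rejects_inconsistent_window_count():
    ws = WindowSet(nn.Tensor(np.zeros((3, 4, 1))), 2, 4, 4, batch=1)
    with pytest.raises(ValueError, match="inconsistent"):
        reverse_windows(ws)


# -- cyclic shift -------------------------------------------------------------

def test_cyclic_shift_moves_and_inverts(rng):
    g = numbered_grid(4, 4)
    shifted = cyclic_shift(g, 1)
    assert shifted.tokens.data[0, 0, 0] == 5.0  # former token (1, 1)
    assert np.array_equal(cyclic_shift(cyclic_shift(g, 0), 0).tokens.data,
                          g.tokens.data)
    x = rng.normal(size=(1, 25, 2))
    g2 = TokenGrid(nn.Tensor(x), 5, 5)
    back = cyclic_shift(cyclic_shift(g2, 2), -2)
    np.testing.assert_array_equal(back.tokens.data, x)
    with pytest.raises(ValueError):
        cyclic_shift(g, 4)


# -- relative position index --------------------------------------------------

@pytest.mark.parametrize("m", [1, 2, 3, 7])
def test_relative_position_index_matches_displacement_arithmetic(m):
    idx = build_relative_position_index(m)
    assert idx.shape == (m * m, m * m)
    # brute-force re-derivation from (y, x) displacements
    pos = [(i // m, i % m) for i in range(m * m)]
    for i, (yi, xi) in enumerate(pos):
        for j, (yj, xj) in enumerate(pos):
            dy, dx = yi - yj, xi - xj
            assert idx[i, j] == (dy + m - 1) * (2 * m - 1) + (dx + m - 1)
    assert idx.max() <= (2 * m - 1) ** 2 - 1
    # swapping the pair negates the displacement
    flipped = (idx // (2 * m - 1)) + (idx % (2 * m - 1)) * 0  # dy+m-1 part
    np.testing.assert_array_equal(
        idx.T, (2 * (m - 1) - (idx // (2 * m - 1))) * (2 * m - 1)
        + (2 * (m - 1) - idx % (2 * m - 1)))


def test_relative_position_index_examples():
    assert build_relative_position_index(1).tolist() == [[0]]
    idx2 = build_relative_position_index(2)
    assert len(np.unique(idx2)) == 9
    assert np.all(np.diag(idx2) == 4)  # zero displacement slot
    assert build_relative_position_index(7).max() == 168
    with pytest.raises(ValueError):
        build_relative_position_index(0)


# -- window attention ---------------------------------------------------------

@pytest.mark.parametrize("m,heads,d", [(1, 1, 2), (2, 1, 3), (7, 2, 4)])
def test_window_attention_equals_dense_oracle(m, heads, d, rng):
    l = m * m
    q = rng.normal(size=(1, heads, l, d))
    k = rng.normal(size=(1, heads, l, d))
    v = rng.normal(size=(1, heads, l, d))
    table = rng.normal(size=((2 * m - 1) ** 2, heads))
    ri = build_relative_position_index(m)
    out = window_attention(
        AttentionInputs(q, k, v, table, ri, heads, d)).data[0]
    for h in range(heads):
        want = dense_window_attention_oracle(q[0, h], k[0, h], v[0, h],
                                             table[ri, h])
        np.testing.assert_allclose(out[:, h * d:(h + 1) * d], want, atol=1e-6)


def test_window_attention_uniform_and_single_token(rng):
    m, d = 2, 3
    ri = build_relative_position_index(m)
    v = rng.normal(size=(1, 1, 4, d))
    # zero queries and zero bias: softmax is uniform, rows = column mean of V
    out = window_attention(AttentionInputs(
        np.zeros((1, 1, 4, d)), rng.normal(size=(1, 1, 4, d)), v,
        np.zeros((9, 1)), ri, 1, d))
    np.testing.assert_allclose(out.data[0], np.tile(v[0, 0].mean(0), (4, 1)),
                               atol=1e-12)
    # M=1: softmax of a scalar is 1, output is V
    v1 = rng.normal(size=(1, 1, 1, d))
    out1 = window_attention(AttentionInputs(
        rng.normal(size=(1, 1, 1, d)), rng.normal(size=(1, 1, 1, d)), v1,
        rng.normal(size=(1, 1)), build_relative_position_index(1), 1, d))
    np.testing.assert_allclose(out1.data, v1[:, 0], atol=1e-12)


def test_window_attention_rejects_bad_inputs(rng):
    ri = build_relative_position_index(2)
    q = rng.normal(size=(1, 1, 4, 3))
    with pytest.raises(ValueError, match="mismatch"):
        window_attention(AttentionInputs(q, q[..., :2], q, np.zeros((9, 1)),
                                         ri, 1, 3))
    bad = q.copy()
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        window_attention(AttentionInputs(bad, q, q, np.zeros((9, 1)), ri, 1, 3))


def test_attention_output_is_convex_combination_of_values(rng):
    """Rows of the attention matrix are a probability distribution for any
    bias and mask, so outputs stay inside the convex hull of V."""
    m, d = 3, 2
    ri = build_relative_position_index(m)
    v = rng.normal(size=(1, 1, 9, d))
    mask = np.where(rng.random((9, 9)) < 0.3, swin.NEG_INF, 0.0)
    np.fill_diagonal(mask, 0.0)
    out = window_attention(AttentionInputs(
        rng.normal(size=(1, 1, 9, d)), rng.normal(size=(1, 1, 9, d)), v,
        rng.normal(size=(25, 1)) * 3, ri, 1, d), mask).data[0]
    assert out.min() >= v.min() - 1e-9 and out.max() <= v.max() + 1e-9


def test_windowed_equals_global_attention_when_window_covers_grid(rng):
    """With M = H = W and no shift, window attention is global attention."""
    m = 4
    layer = swin.WindowAttention(dim=8, num_heads=2, window_size=m,
                                 rng=np.random.default_rng(3))
    x = rng.normal(size=(1, m * m, 8))
    got = layer(nn.Tensor(x)).data[0]
    # dense oracle using the layer's own weights
    qkv = x @ layer.qkv.weight.data + layer.qkv.bias.data
    qkv = qkv.reshape(m * m, 3, 2, 4).transpose(1, 2, 0, 3)
    heads = []
    for h in range(2):
        bias = layer.bias_table.data[layer.relative_index, h]
        heads.append(dense_window_attention_oracle(
            qkv[0, h], qkv[1, h], qkv[2, h], bias))
    want = np.concatenate(heads, axis=-1) @ layer.proj.weight.data \
        + layer.proj.bias.data
    np.testing.assert_allclose(got, want, atol=1e-6)


# -- shift masks --------------------------------------------------------------

def test_shift_mask_zero_and_bounds():
    sm = build_shift_mask(4, 4, 2, 0)
    assert np.all(sm.mask == 0)
    with pytest.raises(ValueError):
        build_shift_mask(4, 4, 2, 2)


def test_shift_mask_matches_brute_force_region_labelling():
    h = w = m = 4
    s = m // 2
    sm = build_shift_mask(h, w, m, s)
    labels = swin.shift_region_labels(h, w, m, s)
    rolled = np.roll(labels, (-s, -s), axis=(0, 1)).reshape(-1)
    brute = np.where(rolled[:, None] != rolled[None, :], swin.NEG_INF, 0.0)
    np.testing.assert_array_equal(sm.mask[0], brute)
    # mask is symmetric, entries only {0, NEG_INF}
    np.testing.assert_array_equal(sm.mask[0], sm.mask[0].T)
    assert set(np.unique(sm.mask)) <= {0.0, swin.NEG_INF}


def test_masked_attention_gives_zero_weight_across_regions(rng):
    """With region-indicator values, masked attention output for a token has
    no contribution from foreign regions."""
    h = w = m = 4
    s = 2
    sm = build_shift_mask(h, w, m, s)
    labels = np.roll(swin.shift_region_labels(h, w, m, s), (-s, -s),
                     axis=(0, 1)).reshape(-1)
    onehot = (labels[:, None] == np.unique(labels)[None, :]).astype(float)
    ri = build_relative_position_index(m)
    out = window_attention(AttentionInputs(
        rng.normal(size=(1, 1, 16, 3)), rng.normal(size=(1, 1, 16, 3)),
        onehot[None, None], np.zeros(((2 * m - 1) ** 2, 1)), ri, 1,
        onehot.shape[1]), sm.mask[0]).data[0]
    for i, lab in enumerate(labels):
        own = np.flatnonzero(np.unique(labels) == lab)[0]
        foreign = np.delete(np.arange(onehot.shape[1]), own)
        assert out[i, foreign].max() < 1e-8  # total foreign attention weight
        assert np.isclose(out[i, own], 1.0, atol=1e-8)


# -- swin block ---------------------------------------------------------------

def test_swin_block_is_identity_under_zero_weights(rng):
    blk = SwinBlock(8, 2, 4, shift=2)
    for name, p in blk.named_parameters():
        if not ("norm" in name and name.endswith("weight")):
            p.data = np.zeros_like(p.data)
    x = rng.normal(size=(2, 36, 8))
    out = blk(nn.Tensor(x), 6, 6)  # exercises the padding path too
    np.testing.assert_allclose(out.data, x, atol=1e-12)


@pytest.mark.parametrize("hw", [(8, 8), (7, 5), (4, 12)])
def test_swin_block_preserves_shape(hw, rng):
    h, w = hw
    blk = SwinBlock(6, 2, 4, shift=2, rng=np.random.default_rng(1))
    x = rng.normal(size=(1, h * w, 6))
    assert blk(nn.Tensor(x), h, w).shape == (1, h * w, 6)


def test_swin_block_rejects_channel_mismatch(rng):
    blk = SwinBlock(6, 2, 4)
    with pytest.raises(ValueError, match="channel mismatch"):
        blk(nn.Tensor(rng.normal(size=(1, 16, 5))), 4, 4)


def test_swin_block_equals_hand_composed_sequence(rng):
    """Forward of one unshifted block == LN -> attention -> add -> LN -> MLP
    -> add composed by hand on a window-sized grid."""
    blk = SwinBlock(8, 2, 4, shift=0, rng=np.random.default_rng(5))
    x = rng.normal(size=(1, 16, 8))
    got = blk(nn.Tensor(x), 4, 4).data
    h1 = blk.norm1(nn.Tensor(x)).data
    attn = blk.attn(nn.Tensor(h1.reshape(1, 16, 8))).data  # one window = grid
    y = x + attn
    z = y + blk.mlp(blk.norm2(nn.Tensor(y))).data
    np.testing.assert_allclose(got, z, atol=1e-6)


def test_swin_block_gradient_on_two_token_toy(gradcheck, rng):
    blk = SwinBlock(2, 1, 1, shift=0, rng=np.random.default_rng(2))
    gradcheck(lambda x: blk(x, 1, 2), rng.normal(size=(1, 2, 2)), tol=1e-4)


# -- patch embed / merge / expand --------------------------------------------

def test_patch_embed_dimensions(rng):
    pe = PatchEmbed(3, 4, 96)
    assert pe.raw_dim == 48  # 4 x 4 x 3
    g = pe(nn.Tensor(rng.normal(size=(1, 3, 224, 224))))
    assert (g.grid_height, g.grid_width, g.channels) == (56, 56, 96)
    assert g.tokens.shape[1] == 3136
    g1 = PatchEmbed(3, 4, 8)(nn.Tensor(rng.normal(size=(1, 3, 4, 4))))
    assert g1.tokens.shape[1] == 1
    raw, gh, gw = swin.extract_patches(nn.Tensor(rng.normal(size=(1, 1, 8, 8))), 4)
    assert raw.shape == (1, 4, 16) and (gh, gw) == (2, 2)
    with pytest.raises(ValueError):
        PatchEmbed(3, 4, 8)(nn.Tensor(rng.normal(size=(1, 3, 6, 6))))


def test_patch_merge_shapes_and_gather(rng):
    pm = PatchMerging(4, rng=np.random.default_rng(1))
    g = TokenGrid(nn.Tensor(rng.normal(size=(1, 56 * 56, 4))), 56, 56)
    out = pm(g)
    assert (out.grid_height, out.grid_width, out.channels) == (28, 28, 8)
    assert out.tokens.shape[1] == g.tokens.shape[1] // 4
    with pytest.raises(ValueError):
        pm(TokenGrid(nn.Tensor(rng.normal(size=(1, 15, 4))), 3, 5))
    # identity-style reduction: pick out the first input token of each 2x2 cell
    pm.norm.weight.data = np.ones(16)
    pm.norm.bias.data = np.zeros(16)
    w = np.zeros((16, 8))
    w[:4, :4] = np.eye(4)  # first concatenated token (cell corner (0,0))
    pm.reduction.weight.data = w
    toks = rng.normal(size=(1, 16, 4))
    g2 = TokenGrid(nn.Tensor(toks), 4, 4)
    normed = pm.norm(nn.Tensor(np.concatenate([
        toks[0].reshape(2, 2, 2, 2, 4).transpose(0, 2, 1, 3, 4)[:, :, i // 2, i % 2]
        for i in range(4)], axis=-1).reshape(1, 4, 16))).data
    np.testing.assert_allclose(pm(g2).tokens.data[..., :4], normed[..., :4] @ np.eye(4),
                               atol=1e-9)


def test_patch_expand_and_merge_shape_round_trip(rng):
    px = PatchExpand(8, rng=np.random.default_rng(1))
    g = TokenGrid(nn.Tensor(rng.normal(size=(1, 28 * 28, 8))), 28, 28)
    out = px(g)
    assert (out.grid_height, out.grid_width, out.channels) == (56, 56, 4)
    assert out.tokens.shape[1] == 4 * g.tokens.shape[1]
    with pytest.raises(ValueError):
        PatchExpand(7)
    # merge then expand restores the grid shape and channel count
    pm = PatchMerging(4, rng=np.random.default_rng(2))
    px2 = PatchExpand(8, rng=np.random.default_rng(3))
    g0 = TokenGrid(nn.Tensor(rng.normal(size=(1, 36, 4))), 6, 6)
    back = px2(pm(g0))
    assert (back.grid_height, back.grid_width, back.channels) == (6, 6, 4)


def test_final_expand_resolution_and_locality(rng):
    fx = FinalExpandX4(4, 3, rng=np.random.default_rng(1))
    g = TokenGrid(nn.Tensor(rng.normal(size=(1, 56 * 56, 4))), 56, 56)
    assert fx(g).shape == (1, 3, 224, 224)
    g16 = TokenGrid(nn.Tensor(rng.normal(size=(1, 256, 4))), 16, 16)
    assert fx(g16).shape == (1, 3, 64, 64)
    # each output pixel depends only on its source token
    base = rng.normal(size=(1, 16, 4))
    out0 = fx(TokenGrid(nn.Tensor(base.copy()), 4, 4)).data
    pert = base.copy()
    pert[0, 5] += 1.0  # token (1, 1)
    out1 = fx(TokenGrid(nn.Tensor(pert), 4, 4)).data
    diff = np.abs(out1 - out0).sum(axis=1)[0]
    ys, xs = np.nonzero(diff > 1e-12)
    assert ys.min() >= 4 and ys.max() < 8 and xs.min() >= 4 and xs.max() < 8


def test_shape_algebra_composition(rng):
    """embed /4, merge /2 x2C, expand x2 /2C, final x4 restores resolution."""
    pe = PatchEmbed(1, 4, 6, rng=np.random.default_rng(1))
    pm = PatchMerging(6, rng=np.random.default_rng(2))
    px = PatchExpand(12, rng=np.random.default_rng(3))
    fx = FinalExpandX4(6, 2, rng=np.random.default_rng(4))
    img = nn.Tensor(rng.normal(size=(1, 1, 32, 32)))
    out = fx(px(pm(pe(img))))
    assert out.shape == (1, 2, 32, 32)
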