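"""Shifted-window transformer machinery.

Implements the token-grid currency of the transformer branch: window
partition/reverse, relative-position-indexed window attention, the
W-MSA/SW-MSA residual block pair, patch embedding, patch merging and patch
expanding.  Window attention restricts self-attention to M x M token
windows; alternate blocks shift the window grid by floor(M/2) tokens
(cyclically) so information propagates across window boundaries, with an
additive mask preventing attention between tokens that were not neighbours
before the cyclic shift.

Token layout is row-major: a grid of H x W tokens with C channels is stored
as a (batch, H*W, C) tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

NEG_INF = -1e9  # additive mask value; exp(NEG_INF) underflows to exactly 0


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class TokenGrid:
    """A sequence of patch tokens with implicit (H, W) grid semantics."""

    tokens: Tensor  # (B, H*W, C)
    grid_height: int
    grid_width: int

    def __post_init__(self):
        self.tokens = as_tensor(self.tokens)
        if self.tokens.ndim == 2:  # allow unbatched matrices
            self.tokens = self.tokens.reshape(1, *self.tokens.shape)
        b, l, _ = self.tokens.shape
        if l != self.grid_height * self.grid_width:
            raise ValueError(
                f"token count {l} != grid {self.grid_height}x{self.grid_width}")

    @property
    def channels(self) -> int:
        return self.tokens.shape[-1]

    @property
    def batch(self) -> int:
        return self.tokens.shape[0]


@dataclass
class WindowSet:
    """Non-overlapping M x M windows cut from a token grid."""

    windows: Tensor  # (B * nW, M*M, C)
    window_size: int
    source_height: int
    source_width: int
    batch: int = 1

    @property
    def num_windows(self) -> int:
        return (self.source_height // self.window_size) * \
            (self.source_width // self.window_size)


@dataclass
class AttentionInputs:
    """Per-head query/key/value plus the relative-position bias machinery."""

    q: Tensor  # (..., num_heads, M*M, d)
    k: Tensor
    v: Tensor
    bias_table: Tensor  # ((2M-1)**2, num_heads)
    relative_index: np.ndarray  # (M*M, M*M) ints in [0, (2M-1)**2)
    num_heads: int
    head_dim: int


@dataclass
class ShiftMask:
    """Additive attention mask for one window layout: entries 0 or NEG_INF."""

    mask: np.ndarray  # (nW, M*M, M*M)
    shift: int


# ---------------------------------------------------------------------------
# window partition / reverse / shift
# ---------------------------------------------------------------------------

def partition_windows(grid: TokenGrid, window_size: int) -> WindowSet:
    """Tile the token grid into non-overlapping M x M windows (row-major)."""
    h, w, m = grid.grid_height, grid.grid_width, window_size
    if h % m or w % m:
        raise ValueError(
            f"grid {h}x{w} not divisible by window size {m}; pad first")
    b, _, c = grid.tokens.shape
    x = grid.tokens.reshape(b, h // m, m, w // m, m, c)
    x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(-1, m * m, c)
    return WindowSet(x, m, h, w, batch=b)


def reverse_windows(ws: WindowSet) -> TokenGrid:
    """Exact inverse of :func:`partition_windows`."""
    m, h, w, b = ws.window_size, ws.source_height, ws.source_width, ws.batch
    expected = b * (h // m) * (w // m)
    if ws.windows.shape[0] != expected:
        raise ValueError(
            f"window count {ws.windows.shape[0]} inconsistent with "
            f"{h}x{w} grid at window size {m} (expected {expected})")
    c = ws.windows.shape[-1]
    x = ws.windows.reshape(b, h // m, w // m, m, m, c)
    x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, h * w, c)
    return TokenGrid(x, h, w)


def cyclic_shift(grid: TokenGrid, shift: int) -> TokenGrid:
    """Toroidal roll of the token grid by (-shift, -shift)."""
    h, w = grid.grid_height, grid.grid_width
    if abs(shift) >= min(h, w):
        raise ValueError(f"|shift|={abs(shift)} must be < min(H, W)={min(h, w)}")
    b, _, c = grid.tokens.shape
    x = grid.tokens.reshape(b, h, w, c)
    x = nn.roll2d(x, (-shift, -shift), (1, 2))
    return TokenGrid(x.reshape(b, h * w, c), h, w)


# ---------------------------------------------------------------------------
# relative position bias
# ---------------------------------------------------------------------------

def build_relative_position_index(window_size: int) -> np.ndarray:
    """Index matrix mapping token pairs to bias-table rows.

    Entry (i, j) is (dy + M - 1) * (2M - 1) + (dx + M - 1) where (dy, dx)
    is the grid displacement from token j to token i; in-window relative
    positions along each axis lie in [-M+1, M-1], giving (2M-1)**2 slots.
    """
    m = int(window_size)
    if m < 1:
        raise ValueError("window size must be >= 1")
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    coords = coords.reshape(2, -1)  # (2, M*M) of (y, x)
    rel = coords[:, :, None] - coords[:, None, :]  # (2, M*M, M*M), j -> i
    return (rel[0] + m - 1) * (2 * m - 1) + (rel[1] + m - 1)


# ---------------------------------------------------------------------------
# attention masks
# ---------------------------------------------------------------------------

def _window_labels(labels: np.ndarray, m: int) -> np.ndarray:
    """Partition a (H, W) label image into (nW, M*M) window labels."""
    h, w = labels.shape
    lw = labels.reshape(h // m, m, w // m, m).transpose(0, 2, 1, 3)
    return lw.reshape(-1, m * m)


def mask_from_labels(labels: np.ndarray, m: int) -> np.ndarray:
    """Per-window additive mask forbidding attention across label regions."""
    lw = _window_labels(labels, m)
    return np.where(lw[:, :, None] != lw[:, None, :], NEG_INF, 0.0)


def shift_region_labels(h: int, w: int, m: int, s: int) -> np.ndarray:
    """Label each grid position by its pre-shift region (9 blocks max)."""
    labels = np.zeros((h, w), dtype=np.int64)
    if s == 0:
        return labels
    cnt = 0
    hs = (slice(0, h - m), slice(h - m, h - s), slice(h - s, h))
    wslices = (slice(0, w - m), slice(w - m, w - s), slice(w - s, w))
    for hsl in hs:
        for wsl in wslices:
            labels[hsl, wsl] = cnt
            cnt += 1
    return labels


def build_shift_mask(h: int, w: int, m: int, s: int) -> ShiftMask:
    """Mask for SW-MSA: token pairs from different pre-shift regions get
    NEG_INF so the cyclic shift cannot make wrapped tokens attend across
    the original image boundary.  ``s`` is the shift in tokens, 0 <= s < M."""
    if not 0 <= s < m:
        raise ValueError(f"shift {s} must satisfy 0 <= s < window size {m}")
    if h % m or w % m:
        raise ValueError(f"grid {h}x{w} not divisible by window size {m}")
    labels = shift_region_labels(h, w, m, s)
    rolled = np.roll(labels, (-s, -s), axis=(0, 1))
    return ShiftMask(mask_from_labels(rolled, m), s)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def window_attention(inp: AttentionInputs, mask: ShiftMask | np.ndarray | None = None
                     ) -> Tensor:
    """Scaled dot-product attention with relative position bias.

    Per head computes softmax(Q K^T / sqrt(d) + B [+ mask]) V, where B is
    the bias table gathered through the relative-position index; heads are
    concatenated along channels.  Output shape (..., M*M, num_heads * d).
    """
    q, k, v = as_tensor(inp.q), as_tensor(inp.k), as_tensor(inp.v)
    for name, t in (("q", q), ("k", k), ("v", v)):
        if np.isnan(t.data).any():
            raise ValueError(f"NaN in attention input {name}")
    if q.shape != k.shape or k.shape[:-2] != v.shape[:-2] \
            or k.shape[-2] != v.shape[-2]:
        raise ValueError(f"attention shape mismatch: q{q.shape} k{k.shape} v{v.shape}")
    d = inp.head_dim
    if d <= 0:
        raise ValueError("head dimension must be positive")

    scale = 1.0 / np.sqrt(d)
    attn = nn.matmul(q * scale, k.transpose(tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2)))
    bias = as_tensor(inp.bias_table)[inp.relative_index]  # (M*M, M*M, heads)
    attn = attn + bias.transpose((2, 0, 1))
    if mask is not None:
        mdata = mask.mask if isinstance(mask, ShiftMask) else np.asarray(mask)
        attn = attn + Tensor(mdata)
    attn = nn.softmax(attn, axis=-1)
    out = nn.matmul(attn, v)  # (..., heads, M*M, d)
    nd = out.ndim
    out = out.transpose(tuple(range(nd - 3)) + (nd - 2, nd - 3, nd - 1))
    return out.reshape(*out.shape[:-2], inp.num_heads * d)


class WindowAttention(nn.Module):
    """Multi-head window attention layer with learned relative position bias."""

    def __init__(self, dim: int, num_heads: int, window_size: int, rng=None):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by {num_heads} heads")
        self.dim, self.num_heads, self.window_size = dim, num_heads, window_size
        self.head_dim = dim // num_heads
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.bias_table = nn.trunc_normal_(((2 * window_size - 1) ** 2, num_heads),
                                           rng=rng)
        self.relative_index = build_relative_position_index(window_size)

    def forward(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """``xw``: (num_windows_total, M*M, C); ``mask``: broadcastable
        (num_windows_total, M*M, M*M) additive mask or None."""
        nw, l, c = xw.shape
        qkv = self.qkv(xw).reshape(nw, l, 3, self.num_heads, self.head_dim)
        qkv = qkv.transpose((2, 0, 3, 1, 4))  # (3, nW, heads, L, d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        inp = AttentionInputs(q, k, v, self.bias_table, self.relative_index,
                              self.num_heads, self.head_dim)
        m = None if mask is None else mask[:, None]  # broadcast over heads
        return self.proj(window_attention(inp, m))


class Mlp(nn.Module):
    """Token-wise 2-layer MLP with GELU."""

    def __init__(self, dim: int, hidden_ratio: float = 4.0, rng=None):
        super().__init__()
        hidden = int(dim * hidden_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.act = nn.GELU()
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.act(self.fc1(x)))


class SwinBlock(nn.Module):
    """One transformer block: pre-norm (S)W-MSA with residual, then
    pre-norm MLP with residual.  ``shift`` > 0 selects the shifted variant.

    Grids not divisible by the window are zero-padded right/bottom before
    partitioning and cropped after; padded positions are masked out of
    attention.  When the grid is no larger than the window, the window is
    clamped to the grid and shifting is disabled (it would be a no-op
    modulo the window).
    """

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 shift: int = 0, mlp_ratio: float = 4.0, rng=None):
        super().__init__()
        self.dim, self.window_size, self.shift = dim, window_size, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window_size, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, rng=rng)
        self._mask_cache: dict[tuple, np.ndarray | None] = {}

    def _layout(self, h: int, w: int) -> tuple[int, int]:
        m, s = self.window_size, self.shift
        if min(h, w) <= m:
            m, s = min(h, w), 0
        return m, s

    def _mask(self, h: int, w: int) -> np.ndarray | None:
        m, s = self._layout(h, w)
        hp = -(-h // m) * m
        wp = -(-w // m) * m
        key = (h, w)
        if key in self._mask_cache:
            return self._mask_cache[key]
        if s == 0 and hp == h and wp == w:
            mask = None
        else:
            labels = shift_region_labels(hp, wp, m, s)
            labels[h:, :] = -1  # padded rows/cols form their own region
            labels[:, w:] = -1
            rolled = np.roll(labels, (-s, -s), axis=(0, 1))
            mask = mask_from_labels(rolled, m)
        self._mask_cache[key] = mask
        return mask

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        if x.shape[-1] != self.dim:
            raise ValueError(f"channel mismatch: got {x.shape[-1]}, block dim {self.dim}")
        b = x.shape[0]
        m, s = self._layout(h, w)
        hp = -(-h // m) * m
        wp = -(-w // m) * m

        shortcut = x
        x = self.norm1(x)
        grid4 = x.reshape(b, h, w, self.dim)
        if hp != h or wp != w:
            grid4 = nn.pad(grid4, ((0, 0), (0, hp - h), (0, wp - w), (0, 0)))
        grid = TokenGrid(grid4.reshape(b, hp * wp, self.dim), hp, wp)
        if s:
            grid = cyclic_shift(grid, s)
        ws = partition_windows(grid, m)
        mask = self._mask(h, w)
        if mask is not None:
            mask = np.tile(mask, (b, 1, 1))
        attn_out = self.attn(ws.windows, mask)
        grid = reverse_windows(WindowSet(attn_out, m, hp, wp, batch=b))
        if s:
            grid = cyclic_shift(grid, -s)
        out = grid.tokens.reshape(b, hp, wp, self.dim)
        if hp != h or wp != w:
            out = out[:, :h, :w, :]
        x = shortcut + out.reshape(b, h * w, self.dim)
        return x + self.mlp(self.norm2(x))


class SwinStage(nn.Module):
    """A run of blocks at one resolution, alternating W-MSA / SW-MSA."""

    def __init__(self, dim: int, depth: int, num_heads: int, window_size: int,
                 rng=None):
        super().__init__()
        self.blocks = nn.ModuleList([
            SwinBlock(dim, num_heads, window_size,
                      shift=0 if i % 2 == 0 else window_size // 2, rng=rng)
            for i in range(depth)
        ])

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        for blk in self.blocks:
            x = blk(x, h, w)
        return x


# ---------------------------------------------------------------------------
# patch embedding / merging / expanding
# ---------------------------------------------------------------------------

def extract_patches(image: Tensor, patch: int) -> tuple[Tensor, int, int]:
    """Cut an NCHW image into non-overlapping patch vectors.

    Returns raw tokens of dimension patch**2 * channels (e.g. a 4x4 patch of
    an RGB image gives 4*4*3 = 48) and the token-grid height/width.
    """
    image = as_tensor(image)
    b, c, h, w = image.shape
    if h % patch or w % patch:
        raise ValueError(f"image {h}x{w} not divisible by patch size {patch}")
    gh, gw = h // patch, w // patch
    x = image.reshape(b, c, gh, patch, gw, patch)
    x = x.transpose((0, 2, 4, 1, 3, 5)).reshape(b, gh * gw, c * patch * patch)
    return x, gh, gw


class PatchEmbed(nn.Module):
    """Patchify + linear embedding to C channels (+ LayerNorm)."""

    def __init__(self, in_channels: int, patch: int, embed_dim: int, rng=None):
        super().__init__()
        self.patch = patch
        self.raw_dim = patch * patch * in_channels
        self.proj = nn.Linear(self.raw_dim, embed_dim, rng=rng)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, image: Tensor) -> TokenGrid:
        raw, gh, gw = extract_patches(image, self.patch)
        return TokenGrid(self.norm(self.proj(raw)), gh, gw)


class PatchMerging(nn.Module):
    """2x spatial downsampling: concatenate 2x2 token neighbourhoods (4C)
    then linearly reduce to 2C."""

    def __init__(self, dim: int, rng=None):
        super().__init__()
        self.dim = dim
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h, w = grid.grid_height, grid.grid_width
        if h % 2 or w % 2:
            raise ValueError(f"patch merging needs even dims, got {h}x{w}")
        b, _, c = grid.tokens.shape
        x = grid.tokens.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, (h // 2) * (w // 2), 4 * c)
        return TokenGrid(self.reduction(self.norm(x)), h // 2, w // 2)


class PatchExpand(nn.Module):
    """2x spatial upsampling: linear expand C -> 2C, then rearrange the
    doubled channels into a 2x2 block of C/2-channel tokens."""

    def __init__(self, dim: int, rng=None):
        super().__init__()
        if dim % 2:
            raise ValueError(f"patch expand needs even channel count, got {dim}")
        self.dim = dim
        self.expand = nn.Linear(dim, 2 * dim, bias=False, rng=rng)
        self.norm = nn.LayerNorm(dim // 2)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h, w = grid.grid_height, grid.grid_width
        b = grid.batch
        c = self.dim
        x = self.expand(grid.tokens)  # (B, L, 2C)
        x = x.reshape(b, h, w, 2, 2, c // 2)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, 4 * h * w, c // 2)
        return TokenGrid(self.norm(x), 2 * h, 2 * w)


class FinalExpandX4(nn.Module):
    """Final 4x upsampling of the token grid back to pixel resolution,
    followed by a linear per-pixel projection to class logits (NCHW)."""

    def __init__(self, dim: int, num_classes: int, rng=None):
        super().__init__()
        self.dim = dim
        self.expand = nn.Linear(dim, 16 * dim, bias=False, rng=rng)
        self.norm = nn.LayerNorm(dim)
        self.head = nn.Linear(dim, num_classes, rng=rng)

    def forward(self, grid: TokenGrid) -> Tensor:
        h, w = grid.grid_height, grid.grid_width
        b, c = grid.batch, self.dim
        x = self.expand(grid.tokens)  # (B, L, 16C)
        x = x.reshape(b, h, w, 4, 4, c)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, 16 * h * w, c)
        x = self.head(self.norm(x))  # (B, 16L, K)
        k = x.shape[-1]
        x = x.reshape(b, 4 * h, 4 * w, k)
        return x.transpose((0, 3, 1, 2))


def tokens_to_map(grid: TokenGrid) -> Tensor:
    """Reshape a token grid (B, H*W, C) to a dense NCHW feature map."""
    b, _, c = grid.tokens.shape
    x = grid.tokens.reshape(b, grid.grid_height, grid.grid_width, c)
    return x.transpose((0, 3, 1, 2))


def map_to_tokens(x: Tensor) -> TokenGrid:
    """Reshape a dense NCHW feature map to a token grid."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    return TokenGrid(x.transpose((0, 2, 3, 1)).reshape(b, h * w, c), h, w)
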