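"""Assembly of the O-shaped dual-branch segmentation/classification network.

Two encoders — a shifted-window transformer and an MBConv CNN — read the
same image and emit feature pyramids at strides 4, 8, ..., 4 * 2**(S-1).
Both pyramids are projected into a shared "canonical" skip space (the
transformer's channel schedule C, 2C, 4C, ...) and fused element-wise
(optionally concat + 1x1 reduce).  Two decoders — a patch-expanding
transformer decoder and a U-Net style CNN decoder — consume the fused
pyramid and each produce full-resolution class logits; the final
segmentation is the element-wise mean of the enabled decoders' logits.
Any of the four branches can be disabled, giving the 3 x 3 grid of
encoder/decoder combinations used in ablations.

For classification the decoders are dropped: the encoders' bottleneck
(highest-stride) features are concatenated, globally average-pooled and
passed through a fully connected layer.  The encoder weights of a trained
segmentation model can be copied into the classifier
(:func:`transfer_encoder_weights`) to warm-start it.

Branch parameter accounting is strictly additive: every projection a branch
needs to speak the canonical skip space belongs to that branch, so enabling
or disabling a branch changes the total parameter count by exactly that
branch's parameters (the default fusions are parameter-free).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .cnn import (CNNDecoderBlock, EfficientNet, FeatureMap, SegHead)
from .nn import Tensor, as_tensor
from .swin import (FinalExpandX4, PatchEmbed, PatchExpand, PatchMerging,
                   SwinStage, TokenGrid, map_to_tokens, tokens_to_map)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SwinSettings:
    embed_dim: int = 96
    depths: tuple = (2, 2, 6, 2)
    heads: tuple = (3, 6, 12, 24)
    window: int = 7
    patch: int = 4
    mlp_ratio: float = 4.0


@dataclass
class CNNSettings:
    variant: str = "b3"


@dataclass
class BranchSettings:
    use_swin_encoder: bool = True
    use_cnn_encoder: bool = True
    use_swin_decoder: bool = True
    use_cnn_decoder: bool = True


@dataclass
class FusionSettings:
    encoder_mode: str = "add"    # "add" | "concat"
    output_mode: str = "mean"    # "mean" | "sum"


@dataclass
class ONetConfig:
    image_size: int = 224
    in_channels: int = 3
    num_classes: int = 9
    num_classification_classes: int = 3
    swin: SwinSettings = field(default_factory=SwinSettings)
    cnn: CNNSettings = field(default_factory=CNNSettings)
    branches: BranchSettings = field(default_factory=BranchSettings)
    fusion: FusionSettings = field(default_factory=FusionSettings)

    def __post_init__(self):
        if isinstance(self.swin, dict):
            self.swin = SwinSettings(**self.swin)
        if isinstance(self.cnn, dict):
            self.cnn = CNNSettings(**self.cnn)
        if isinstance(self.branches, dict):
            self.branches = BranchSettings(**self.branches)
        if isinstance(self.fusion, dict):
            self.fusion = FusionSettings(**self.fusion)
        self.swin.depths = tuple(self.swin.depths)
        self.swin.heads = tuple(self.swin.heads)
        b = self.branches
        if not (b.use_swin_encoder or b.use_cnn_encoder):
            raise ValueError("at least one encoder branch must be enabled")
        if not (b.use_swin_decoder or b.use_cnn_decoder):
            raise ValueError("at least one decoder branch must be enabled")
        if self.swin.patch != 4:
            raise ValueError("patch size is fixed at 4")
        if len(self.swin.depths) != len(self.swin.heads):
            raise ValueError("depths and heads must have equal length")
        if self.fusion.encoder_mode not in ("add", "concat"):
            raise ValueError("fusion.encoder_mode must be 'add' or 'concat'")
        if self.fusion.output_mode not in ("mean", "sum"):
            raise ValueError("fusion.output_mode must be 'mean' or 'sum'")

    # canonical skip space -------------------------------------------------
    @property
    def num_stages(self) -> int:
        return len(self.swin.depths)

    @property
    def stage_dims(self) -> list[int]:
        return [self.swin.embed_dim * 2 ** i for i in range(self.num_stages)]

    @property
    def stage_strides(self) -> list[int]:
        return [self.swin.patch * 2 ** i for i in range(self.num_stages)]

    @property
    def total_stride(self) -> int:
        return self.stage_strides[-1]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ONetConfig":
        return cls(**d)


def tiny_config(image_size: int = 64, in_channels: int = 1,
                num_classes: int = 4, **overrides) -> ONetConfig:
    """Desk-scale configuration: C=24, depths (1, 1), window 4, tiny CNN."""
    cfg = dict(
        image_size=image_size, in_channels=in_channels, num_classes=num_classes,
        swin=SwinSettings(embed_dim=24, depths=(1, 1), heads=(2, 2), window=4),
        cnn=CNNSettings(variant="tiny"),
    )
    cfg.update(overrides)
    return ONetConfig(**cfg)


# ---------------------------------------------------------------------------
# projections between the two currencies
# ---------------------------------------------------------------------------

class TokensToGrid(nn.Module):
    """Per-token linear map followed by reshape to a dense NCHW map."""

    def __init__(self, in_dim: int, out_channels: int, rng=None):
        super().__init__()
        self.proj = nn.Linear(in_dim, out_channels, rng=rng)

    def forward(self, grid: TokenGrid) -> Tensor:
        out = TokenGrid(self.proj(grid.tokens), grid.grid_height, grid.grid_width)
        return tokens_to_map(out)


class GridToTokens(nn.Module):
    """Reshape a dense NCHW map to tokens then linearly embed them."""

    def __init__(self, in_channels: int, out_dim: int, rng=None):
        super().__init__()
        self.proj = nn.Linear(in_channels, out_dim, rng=rng)

    def forward(self, x: Tensor) -> TokenGrid:
        tg = map_to_tokens(x)
        return TokenGrid(self.proj(tg.tokens), tg.grid_height, tg.grid_width)


def project_tokens_to_grid(grid: TokenGrid, weight, bias=None) -> Tensor:
    """Functional form: tokens (B, L, C) -> map (B, C_out, H, W)."""
    tokens = grid.tokens @ as_tensor(weight)
    if bias is not None:
        tokens = tokens + as_tensor(bias)
    return tokens_to_map(TokenGrid(tokens, grid.grid_height, grid.grid_width))


def project_grid_to_tokens(x: Tensor, weight, bias=None) -> TokenGrid:
    """Functional form: map (B, C, H, W) -> tokens (B, H*W, C_out)."""
    tg = map_to_tokens(x)
    tokens = tg.tokens @ as_tensor(weight)
    if bias is not None:
        tokens = tokens + as_tensor(bias)
    return TokenGrid(tokens, tg.grid_height, tg.grid_width)


def fuse_encoder_features(a: Tensor, b: Tensor, mode: str = "add",
                          reducer: nn.Module | None = None) -> Tensor:
    """Fuse two same-shape feature maps: element-wise add, or channel
    concat followed by a 1x1 reduction."""
    if mode == "add":
        if a.shape != b.shape:
            raise ValueError(f"fusion shape mismatch: {a.shape} vs {b.shape}")
        return a + b
    if mode == "concat":
        if a.shape[0] != b.shape[0] or a.shape[2:] != b.shape[2:]:
            raise ValueError(f"fusion shape mismatch: {a.shape} vs {b.shape}")
        if reducer is None:
            raise ValueError("concat fusion needs a reduction layer")
        return reducer(nn.concat([a, b], axis=1))
    raise ValueError(f"unknown fusion mode {mode!r}")


# ---------------------------------------------------------------------------
# encoder branches (each emits the canonical pyramid)
# ---------------------------------------------------------------------------

class SwinEncoderBranch(nn.Module):
    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        s = cfg.swin
        dims = cfg.stage_dims
        self.patch_embed = PatchEmbed(cfg.in_channels, s.patch, s.embed_dim, rng=rng)
        self.stages = nn.ModuleList([
            SwinStage(dims[i], s.depths[i], s.heads[i], s.window, rng=rng)
            for i in range(cfg.num_stages)
        ])
        self.merges = nn.ModuleList([
            PatchMerging(dims[i], rng=rng) for i in range(cfg.num_stages - 1)
        ])
        # per-stage linear projection from tokens into the canonical
        # C x H x W skip space
        self.out_proj = nn.ModuleList([
            TokensToGrid(dims[i], dims[i], rng=rng) for i in range(cfg.num_stages)
        ])
        self.strides = cfg.stage_strides

    def forward(self, image: Tensor) -> list[FeatureMap]:
        grid = self.patch_embed(image)
        maps = []
        for i, stage in enumerate(self.stages):
            x = stage(grid.tokens, grid.grid_height, grid.grid_width)
            grid = TokenGrid(x, grid.grid_height, grid.grid_width)
            maps.append(FeatureMap(self.out_proj[i](grid), self.strides[i]))
            if i < len(self.merges):
                grid = self.merges[i](grid)
        return maps


class CNNEncoderBranch(nn.Module):
    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        self.backbone = EfficientNet(cfg.cnn.variant, in_channels=cfg.in_channels,
                                     include_head=False,
                                     max_stride=cfg.total_stride, rng=rng)
        self.strides = cfg.stage_strides
        chans = self.backbone.pyramid_channels
        missing = [s for s in self.strides if s not in chans]
        if missing:
            raise ValueError(f"CNN variant {cfg.cnn.variant!r} provides no "
                             f"features at strides {missing}")
        # per-stage 1x1 embedding of the CNN pyramid into the canonical dims
        self.out_proj = nn.ModuleList([
            nn.Conv2d(chans[s], d, 1, rng=rng)
            for s, d in zip(self.strides, cfg.stage_dims)
        ])

    def forward(self, image: Tensor) -> list[FeatureMap]:
        pyr = self.backbone.forward_features(image)
        return [FeatureMap(proj(pyr.at_stride(s).data), s)
                for s, proj in zip(self.strides, self.out_proj)]


# ---------------------------------------------------------------------------
# decoder branches (each consumes the canonical pyramid)
# ---------------------------------------------------------------------------

class SwinDecoderBranch(nn.Module):
    """Patch-expanding transformer decoder with skip fusion.

    Decoder stage depths mirror the encoder's (the stage at a given
    resolution reuses that resolution's encoder depth).
    """

    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        s = cfg.swin
        dims = cfg.stage_dims
        n = cfg.num_stages
        # adapters from canonical maps into token space (owned by this branch)
        self.in_proj = nn.ModuleList([
            GridToTokens(dims[i], dims[i], rng=rng) for i in range(n)
        ])
        self.expands = nn.ModuleList([
            PatchExpand(dims[i], rng=rng) for i in range(n - 1, 0, -1)
        ])
        self.skip_reduce = nn.ModuleList([
            nn.Linear(2 * dims[i], dims[i], bias=False, rng=rng)
            for i in range(n - 2, -1, -1)
        ])
        self.stages = nn.ModuleList([
            SwinStage(dims[i], s.depths[i], s.heads[i], s.window, rng=rng)
            for i in range(n - 2, -1, -1)
        ])
        self.final = FinalExpandX4(dims[0], cfg.num_classes, rng=rng)

    def forward(self, skips: list[FeatureMap]) -> Tensor:
        n = len(skips)
        grid = self.in_proj[n - 1](skips[-1].data)  # bottleneck tokens
        for j, expand in enumerate(self.expands):
            i = n - 2 - j  # target resolution index
            grid = expand(grid)
            skip = self.in_proj[i](skips[i].data)
            fused = nn.concat([grid.tokens, skip.tokens], axis=-1)
            tokens = self.skip_reduce[j](fused)
            tokens = self.stages[j](tokens, grid.grid_height, grid.grid_width)
            grid = TokenGrid(tokens, grid.grid_height, grid.grid_width)
        return self.final(grid)


class CNNDecoderBranch(nn.Module):
    """U-Net style decoder: per-scale upsample + skip concat + double conv,
    then two skip-free blocks back to full resolution and a 1x1 head."""

    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        dims = cfg.stage_dims
        n = cfg.num_stages
        self.blocks = nn.ModuleList([
            CNNDecoderBlock(dims[i], dims[i - 1], dims[i - 1], rng=rng)
            for i in range(n - 1, 0, -1)
        ])
        c4 = dims[0]
        c2 = max(c4 // 2, 8)
        c1 = max(c4 // 4, 8)
        self.up2 = CNNDecoderBlock(c4, 0, c2, rng=rng)
        self.up1 = CNNDecoderBlock(c2, 0, c1, rng=rng)
        self.head = SegHead(c1, cfg.num_classes, rng=rng)

    def forward(self, skips: list[FeatureMap]) -> Tensor:
        x = skips[-1].data
        for j, blk in enumerate(self.blocks):
            i = len(skips) - 2 - j
            x = blk(x, skips[i].data)
        x = self.up2(x)
        x = self.up1(x)
        return self.head(x)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

@dataclass
class SegOutput:
    logits: Tensor                       # (N, num_classes, H, W)
    branch_logits: dict[str, Tensor]     # per enabled decoder

    def argmax_masks(self) -> np.ndarray:
        return np.argmax(self.logits.data, axis=1).astype(np.uint8)


@dataclass
class ClsOutput:
    logits: Tensor                       # (N, num_classification_classes)

    def __post_init__(self):
        if not np.isfinite(self.logits.data).all():
            raise ValueError("classification logits are not finite")

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.logits.data, axis=1)


# ---------------------------------------------------------------------------
# the O-shaped network
# ---------------------------------------------------------------------------

class _EncoderPair(nn.Module):
    """The enabled encoder branches plus canonical-space fusion."""

    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        b = cfg.branches
        self.swin_encoder = SwinEncoderBranch(cfg, rng=rng) if b.use_swin_encoder else None
        self.cnn_encoder = CNNEncoderBranch(cfg, rng=rng) if b.use_cnn_encoder else None
        if cfg.fusion.encoder_mode == "concat" and self.swin_encoder and self.cnn_encoder:
            self.fusion_reduce = nn.ModuleList([
                nn.Conv2d(2 * d, d, 1, rng=rng) for d in cfg.stage_dims
            ])
        else:
            self.fusion_reduce = None

    def forward(self, image: Tensor) -> list[FeatureMap]:
        outs = []
        if self.swin_encoder is not None:
            outs.append(self.swin_encoder(image))
        if self.cnn_encoder is not None:
            outs.append(self.cnn_encoder(image))
        if len(outs) == 1:
            return outs[0]
        fused = []
        for i, (a, b) in enumerate(zip(*outs)):
            reducer = self.fusion_reduce[i] if self.fusion_reduce else None
            fused.append(FeatureMap(
                fuse_encoder_features(a.data, b.data,
                                      mode=self.cfg.fusion.encoder_mode,
                                      reducer=reducer),
                a.stride))
        return fused


class ONet(nn.Module):
    """Dual-encoder dual-decoder segmentation network."""

    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        enc = _EncoderPair(cfg, rng=rng)
        # expose branches at top level for scoped parameter accounting
        self.swin_encoder = enc.swin_encoder
        self.cnn_encoder = enc.cnn_encoder
        self.fusion_reduce = enc.fusion_reduce
        self._encoder = enc
        b = cfg.branches
        self.swin_decoder = SwinDecoderBranch(cfg, rng=rng) if b.use_swin_decoder else None
        self.cnn_decoder = CNNDecoderBranch(cfg, rng=rng) if b.use_cnn_decoder else None

    def _children(self):
        # _encoder shares modules with the top-level attributes; skip it to
        # avoid double counting
        for name, val in self.__dict__.items():
            if name == "_encoder":
                continue
            if isinstance(val, nn.Module):
                yield name, val
            elif isinstance(val, nn.ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def _pad_image(self, image: Tensor) -> tuple[Tensor, int, int]:
        n, c, h, w = image.shape
        s = self.cfg.total_stride
        hp = -(-h // s) * s
        wp = -(-w // s) * s
        if (hp, wp) != (h, w):
            image = nn.pad(image, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)))
        return image, h, w

    def forward(self, image: Tensor) -> SegOutput:
        image = as_tensor(image)
        image, h, w = self._pad_image(image)
        skips = self._encoder(image)
        branch: dict[str, Tensor] = {}
        if self.swin_decoder is not None:
            branch["swin"] = self.swin_decoder(skips)
        if self.cnn_decoder is not None:
            branch["cnn"] = self.cnn_decoder(skips)
        outs = list(branch.values())
        if len(outs) == 1:
            logits = outs[0]
        elif self.cfg.fusion.output_mode == "mean":
            logits = (outs[0] + outs[1]) * 0.5
        else:
            logits = outs[0] + outs[1]
        if logits.shape[2:] != (h, w):
            logits = logits[:, :, :h, :w]
            branch = {k: v[:, :, :h, :w] for k, v in branch.items()}
        return SegOutput(logits, branch)

    def segment(self, image) -> SegOutput:
        return self.forward(image)


class ONetClassifier(nn.Module):
    """Encoder bottleneck -> global average pool -> fully connected head."""

    def __init__(self, cfg: ONetConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        enc = _EncoderPair(cfg, rng=rng)
        self.swin_encoder = enc.swin_encoder
        self.cnn_encoder = enc.cnn_encoder
        # classification pools the branch bottlenecks directly (concatenated
        # when both encoders are enabled); encoder fusion layers are not used
        n_enc = (enc.swin_encoder is not None) + (enc.cnn_encoder is not None)
        self.head = nn.Linear(n_enc * cfg.stage_dims[-1],
                              cfg.num_classification_classes, rng=rng)

    def _bottlenecks(self, image: Tensor) -> Tensor:
        feats = []
        if self.swin_encoder is not None:
            feats.append(self.swin_encoder(image)[-1].data)
        if self.cnn_encoder is not None:
            feats.append(self.cnn_encoder(image)[-1].data)
        return feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)

    def forward(self, image: Tensor) -> ClsOutput:
        image = as_tensor(image)
        n, c, h, w = image.shape
        s = self.cfg.total_stride
        hp, wp = -(-h // s) * s, -(-w // s) * s
        if (hp, wp) != (h, w):
            image = nn.pad(image, ((0, 0), (0, 0), (0, hp - h), (0, wp - w)))
        x = self._bottlenecks(image)
        return ClsOutput(self.head(nn.global_avg_pool(x)))

    def classify(self, image) -> ClsOutput:
        return self.forward(image)


# ---------------------------------------------------------------------------
# parameter accounting and weight transfer
# ---------------------------------------------------------------------------

_ENCODER_PREFIXES = ("swin_encoder.", "cnn_encoder.")
_DECODER_PREFIXES = ("swin_decoder.", "cnn_decoder.")


def count_parameters(model: nn.Module, scope: str = "all") -> int:
    """Total trainable parameter elements in ``scope``
    ('all' | 'encoder' | 'decoder' | a dotted name prefix)."""
    if scope == "all":
        return model.num_parameters()
    if scope == "encoder":
        prefixes = _ENCODER_PREFIXES
    elif scope == "decoder":
        prefixes = _DECODER_PREFIXES
    else:
        prefixes = (scope if scope.endswith(".") else scope + ".",)
    return sum(p.size for name, p in model.named_parameters()
               if name.startswith(prefixes))


def parameter_millions(count: int) -> float:
    return round(count / 1e6, 2)


def transfer_encoder_weights(source: nn.Module, target: nn.Module) -> int:
    """Copy every encoder parameter (and buffer) from ``source`` into
    ``target`` bit-exactly; the target's head is left untouched.

    Returns the number of parameter elements transferred.  Raises on the
    first encoder parameter whose name or shape does not line up.
    """
    src = dict(source.named_parameters())
    dst = dict(target.named_parameters())
    src_enc = {k: v for k, v in src.items() if k.startswith(_ENCODER_PREFIXES)}
    dst_enc = {k: v for k, v in dst.items() if k.startswith(_ENCODER_PREFIXES)}
    for name in sorted(set(src_enc) ^ set(dst_enc)):
        raise ValueError(f"encoder configs differ: parameter {name!r} present "
                         f"in only one model")
    moved = 0
    for name, p_src in src_enc.items():
        p_dst = dst_enc[name]
        if p_src.data.shape != p_dst.data.shape:
            raise ValueError(f"encoder configs differ: {name!r} has shape "
                             f"{p_src.data.shape} vs {p_dst.data.shape}")
        p_dst.data = p_src.data.copy()
        moved += p_src.size
    src_buf = {k: v for k, v in source.named_buffers()
               if k.startswith(_ENCODER_PREFIXES)}
    for name, buf in src_buf.items():
        target._set_buffer(name, buf)
    return moved
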