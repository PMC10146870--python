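"""The segmentation network: a U-shaped CNN encoder/decoder with a
lightweight vision-transformer bottleneck.

Architecture
------------
* Contracting path: the first encoder block applies two stride-1 3x3
  convolutions and one stride-2 convolution; subsequent blocks apply two
  stride-1 convolutions followed by 2x2 max pooling whose argmax indices are
  saved; the last block has no downsampling.  Every convolution is followed
  by batch normalization and ReLU.
* Bottleneck: the deepest CNN feature map is cut into p x p patches in raster
  order (left to right, top to bottom), linearly embedded to width ``vit_dim``
  and processed by a stack of pre-norm transformer blocks whose multi-head
  attention realizes the query/key/value projections as 2-D convolutions over
  the patch grid ("multi-head convolutional attention").  No positional
  encoding is added: spatial information is carried by the convolutional
  projections, the saved pooling indices and the skip connections.  The token
  sequence is projected back and reshaped into a raster of the same size, so
  the bottleneck is shape-preserving and drop-in.
* Expanding path: each decoder stage upsamples by index unpooling (the first
  stage, whose encoder used a strided convolution, upsamples by transposed
  convolution), concatenates the matching encoder skip features, and applies
  two 3x3 convolutions; a final 1x1 convolution maps to K class channels.

Per-pixel class probabilities are the softmax of the K-channel logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig", "TokenSequence", "EncoderState", "SegmentationModel",
    "PatchSerializer", "ConvAttentionHead", "MultiHeadConvAttention",
    "TransformerBlock", "ViTBottleneck", "build_model",
    "ConfigError", "GeometryError",
]


class ConfigError(ValueError):
    """Invalid architecture hyperparameters."""


class GeometryError(ValueError):
    """Input extent incompatible with the downsampling/patching geometry."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_channels`` lists the output width of each encoder block; the
    number of spatial halvings is ``len(encoder_channels) - 1`` (the final
    block does not downsample).  ``attention_kernel=1`` recovers pure linear
    token projections; 3 injects spatial locality over the patch grid.
    """

    in_channels: int = 1
    n_classes: int = 9
    encoder_channels: tuple[int, ...] = (32, 64, 128, 128)
    vit_dim: int = 128
    vit_heads: int = 8
    vit_blocks: int = 4
    vit_mlp_dim: int = 128
    patch_size: int = 2
    use_class_token: bool = False
    attention_kernel: int = 3

    @property
    def n_down_stages(self) -> int:
        return len(self.encoder_channels) - 1

    @property
    def vit_head_dim(self) -> int:
        return self.vit_dim // self.vit_heads

    def validate(self) -> None:
        if self.vit_dim % self.vit_heads != 0:
            raise ConfigError(
                f"vit_dim={self.vit_dim} is not divisible by "
                f"vit_heads={self.vit_heads}")
        if len(self.encoder_channels) < 2:
            raise ConfigError("need at least two encoder blocks")
        if self.attention_kernel % 2 != 1:
            raise ConfigError("attention_kernel must be odd")
        if self.patch_size < 1:
            raise ConfigError("patch_size must be >= 1")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")

    def check_geometry(self, h: int, w: int) -> tuple[int, int]:
        """Validate an input extent; returns the bottleneck extent."""
        div = 2 ** self.n_down_stages
        if h % div or w % div:
            raise GeometryError(
                f"input extent {h}x{w} must be divisible by 2^{self.n_down_stages}"
                f"={div} for exact unpooling")
        hf, wf = h // div, w // div
        if hf % self.patch_size or wf % self.patch_size:
            raise GeometryError(
                f"bottleneck extent {hf}x{wf} must be divisible by "
                f"patch_size={self.patch_size}")
        return hf, wf

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["encoder_channels"] = list(self.encoder_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "encoder_channels" in d:
            d["encoder_channels"] = tuple(d["encoder_channels"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TokenSequence:
    """Serialized patch embeddings: (N, n [+1 class token], d)."""

    tokens: Tensor
    grid: tuple[int, int]          # (rows, cols) of the patch grid
    has_class_token: bool = False

    @property
    def n_spatial(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class EncoderState:
    """Skip features, saved pooling indices and the bottleneck raster."""

    skips: list            # per stage, Tensor feature rasters pre-downsampling
    pool_indices: list     # per pooling stage, int arrays of window argmaxes
    bottleneck: Tensor


# ---- serialization -----------------------------------------------------------

class PatchSerializer(nn.Module):
    """Cuts a (N, C, H, W) raster into p x p patches in raster order and
    embeds each flattened patch to width d; inverts the operation after the
    transformer stack."""

    def __init__(self, channels: int, patch_size: int, dim: int, rng,
                 use_class_token: bool = False):
        super().__init__()
        self.p = patch_size
        self.c = channels
        self.dim = dim
        self.embed = nn.Linear(patch_size * patch_size * channels, dim, rng)
        self.unembed = nn.Linear(dim, patch_size * patch_size * channels, rng)
        self.use_class_token = use_class_token
        if use_class_token:
            self.class_token = nn.modules._param(
                rng.normal(0.0, 0.02, size=(1, 1, dim)))

    def serialize(self, feature: Tensor) -> TokenSequence:
        n, c, h, w = feature.shape
        p = self.p
        if h % p or w % p:
            raise GeometryError(
                f"feature extent {h}x{w} not divisible by patch size {p}")
        gh, gw = h // p, w // p
        # (N,C,gh,p,gw,p) -> (N,gh,gw,p,p,C) -> (N, n, p*p*C)
        x = nn.reshape(feature, (n, c, gh, p, gw, p))
        x = nn.transpose(x, (0, 2, 4, 3, 5, 1))
        x = nn.reshape(x, (n, gh * gw, p * p * c))
        tokens = self.embed(x)
        if self.use_class_token:
            cls = nn.concatenate([self.class_token] * n, axis=0) if n > 1 \
                else self.class_token
            tokens = nn.concatenate([cls, tokens], axis=1)
        return TokenSequence(tokens=tokens, grid=(gh, gw),
                             has_class_token=self.use_class_token)

    def deserialize(self, seq: TokenSequence) -> Tensor:
        tokens = seq.tokens
        if seq.has_class_token:
            tokens = tokens[:, 1:, :]   # the segmentation head never consumes it
        n = tokens.shape[0]
        gh, gw = seq.grid
        p, c = self.p, self.c
        x = self.unembed(tokens)
        x = nn.reshape(x, (n, gh, gw, p, p, c))
        x = nn.transpose(x, (0, 5, 1, 3, 2, 4))
        return nn.reshape(x, (n, c, gh * p, gw * p))


# ---- attention ---------------------------------------------------------------

class ConvAttentionHead(nn.Module):
    """One head of scaled dot-product attention whose Q/K/V projections are
    2-D convolutions over the patch grid.  A class token, having no grid
    position, is projected through an auxiliary linear path."""

    def __init__(self, head_dim: int, kernel: int, rng,
                 use_class_token: bool = False):
        super().__init__()
        self.d_h = head_dim
        self.q_conv = nn.Conv2d(head_dim, head_dim, kernel, rng)
        self.k_conv = nn.Conv2d(head_dim, head_dim, kernel, rng)
        self.v_conv = nn.Conv2d(head_dim, head_dim, kernel, rng)
        if use_class_token:
            self.q_cls = nn.Linear(head_dim, head_dim, rng)
            self.k_cls = nn.Linear(head_dim, head_dim, rng)
            self.v_cls = nn.Linear(head_dim, head_dim, rng)

    def project(self, tokens: Tensor, grid: tuple[int, int],
                has_class_token: bool) -> tuple[Tensor, Tensor, Tensor]:
        gh, gw = grid
        n = tokens.shape[0]
        start = 1 if has_class_token else 0
        spatial = tokens[:, start:, :] if has_class_token else tokens
        # (N, n, d_h) -> (N, d_h, gh, gw)
        x = nn.transpose(nn.reshape(spatial, (n, gh, gw, self.d_h)),
                         (0, 3, 1, 2))

        def back(t):
            return nn.reshape(nn.transpose(t, (0, 2, 3, 1)),
                              (n, gh * gw, self.d_h))

        q, k, v = back(self.q_conv(x)), back(self.k_conv(x)), back(self.v_conv(x))
        if has_class_token:
            cls = tokens[:, 0:1, :]
            q = nn.concatenate([self.q_cls(cls), q], axis=1)
            k = nn.concatenate([self.k_cls(cls), k], axis=1)
            v = nn.concatenate([self.v_cls(cls), v], axis=1)
        return q, k, v

    def forward(self, tokens: Tensor, grid: tuple[int, int],
                has_class_token: bool = False) -> Tensor:
        q, k, v = self.project(tokens, grid, has_class_token)
        return scaled_dot_product_attention(q, k, v)


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_h)) V; every attention row sums to 1."""
    d_h = q.shape[-1]
    scores = nn.matmul(q, nn.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(d_h))
    a = nn.softmax(scores, axis=-1)
    return nn.matmul(a, v)


class MultiHeadConvAttention(nn.Module):
    """Split the token width equally across heads, run convolutional
    attention per head, concatenate along the feature dimension, and mix
    through a linear layer."""

    def __init__(self, dim: int, heads: int, kernel: int, rng,
                 use_class_token: bool = False):
        super().__init__()
        if dim % heads != 0:
            raise ConfigError(f"dim={dim} not divisible by heads={heads}")
        self.dim = dim
        self.heads = [ConvAttentionHead(dim // heads, kernel, rng,
                                        use_class_token)
                      for _ in range(heads)]
        self.mix = nn.Linear(dim, dim, rng)

    def forward(self, tokens: Tensor, grid: tuple[int, int],
                has_class_token: bool = False) -> Tensor:
        d_h = self.dim // len(self.heads)
        outs = []
        for i, head in enumerate(self.heads):
            block = tokens[:, :, i * d_h:(i + 1) * d_h]
            outs.append(head(block, grid, has_class_token))
        return self.mix(nn.concatenate(outs, axis=-1))


class TransformerBlock(nn.Module):
    """Pre-norm transformer block: x + MHA(LN(x)), then + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_dim: int, kernel: int, rng,
                 use_class_token: bool = False):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadConvAttention(dim, heads, kernel, rng,
                                           use_class_token)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp_in = nn.Linear(dim, mlp_dim, rng)
        self.mlp_out = nn.Linear(mlp_dim, dim, rng)

    def forward(self, tokens: Tensor, grid: tuple[int, int],
                has_class_token: bool = False) -> Tensor:
        x = tokens + self.attn(self.norm1(tokens), grid, has_class_token)
        return x + self.mlp_out(nn.relu(self.mlp_in(self.norm2(x))))


class ViTBottleneck(nn.Module):
    """Shape-preserving transformer stack over serialized bottleneck patches."""

    def __init__(self, channels: int, cfg: ModelConfig, rng):
        super().__init__()
        self.serializer = PatchSerializer(channels, cfg.patch_size,
                                          cfg.vit_dim, rng,
                                          cfg.use_class_token)
        self.blocks = [TransformerBlock(cfg.vit_dim, cfg.vit_heads,
                                        cfg.vit_mlp_dim, cfg.attention_kernel,
                                        rng, cfg.use_class_token)
                       for _ in range(cfg.vit_blocks)]

    def forward(self, feature: Tensor) -> Tensor:
        seq = self.serializer.serialize(feature)
        tokens = seq.tokens
        for block in self.blocks:
            tokens = block(tokens, seq.grid, seq.has_class_token)
        out = TokenSequence(tokens=tokens, grid=seq.grid,
                            has_class_token=seq.has_class_token)
        return self.serializer.deserialize(out)


# ---- CNN blocks --------------------------------------------------------------

class _ConvBNReLU(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng, stride: int = 1,
                 kernel: int = 3):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, rng, stride=stride)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class SegmentationModel(nn.Module):
    """Hybrid CNN / vision-transformer encoder-decoder for K-class pixel
    labeling of B-scans."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        ch = config.encoder_channels
        s = len(ch)

        # encoder block 1: conv s1 x2, then conv s2
        self.enc1 = [
            _ConvBNReLU(config.in_channels, ch[0], rng),
            _ConvBNReLU(ch[0], ch[0], rng),
            _ConvBNReLU(ch[0], ch[0], rng, stride=2),
        ]
        # middle blocks (conv x2 then pooling) and the last block (no pool)
        self.enc_mid = []
        for i in range(1, s - 1):
            self.enc_mid.append([
                _ConvBNReLU(ch[i - 1], ch[i], rng),
                _ConvBNReLU(ch[i], ch[i], rng),
            ])
        self.enc_last = [
            _ConvBNReLU(ch[s - 2], ch[s - 1], rng),
            _ConvBNReLU(ch[s - 1], ch[s - 1], rng),
        ]

        self.vit = ViTBottleneck(ch[s - 1], config, rng)

        # decoder mirror: deepest stage (no resolution change), then unpooling
        # stages, then the transposed-convolution stage matching block 1
        self.dec_last = [
            _ConvBNReLU(ch[s - 1], ch[s - 1], rng),
            _ConvBNReLU(ch[s - 1], ch[s - 2], rng),
        ]
        self.dec_mid = []
        for i in range(s - 2, 0, -1):     # stages s-1 .. 2 in forward order
            out_ch = ch[i - 1] if i > 1 else ch[0]
            self.dec_mid.append([
                _ConvBNReLU(2 * ch[i], ch[i], rng),
                _ConvBNReLU(ch[i], out_ch, rng),
            ])
        self.up1 = nn.ConvTranspose2d(ch[0], ch[0], rng)
        self.dec1 = [
            _ConvBNReLU(2 * ch[0], ch[0], rng),
            _ConvBNReLU(ch[0], ch[0], rng),
        ]
        self.head = nn.Conv2d(ch[0], config.n_classes, 1, rng, padding=0)

    # -- encoder ---------------------------------------------------------------
    def encode(self, x: Tensor) -> EncoderState:
        h, w = x.shape[2], x.shape[3]
        self.config.check_geometry(h, w)
        skips = []
        indices = []
        out = self.enc1[0](x)
        out = self.enc1[1](out)
        skips.append(out)                  # full-resolution skip
        out = self.enc1[2](out)            # stride-2 halving
        for block in self.enc_mid:
            out = block[0](out)
            out = block[1](out)
            skips.append(out)
            out, idx = nn.max_pool2d(out)
            indices.append(idx)
        out = self.enc_last[0](out)
        out = self.enc_last[1](out)
        return EncoderState(skips=skips, pool_indices=indices, bottleneck=out)

    # -- decoder ---------------------------------------------------------------
    def decode(self, state: EncoderState, bottleneck: Tensor) -> Tensor:
        if len(state.pool_indices) != len(self.dec_mid):
            raise ValueError(
                f"encoder state holds {len(state.pool_indices)} pooling index "
                f"sets; decoder expects {len(self.dec_mid)}")
        out = self.dec_last[0](bottleneck)
        out = self.dec_last[1](out)
        for j, block in enumerate(self.dec_mid):
            idx = state.pool_indices[-1 - j]
            skip = state.skips[-1 - j]
            out = nn.max_unpool2d(out, idx)
            out = nn.concatenate([out, skip], axis=1)
            out = block[0](out)
            out = block[1](out)
        out = self.up1(out)
        out = nn.concatenate([out, state.skips[0]], axis=1)
        out = self.dec1[0](out)
        out = self.dec1[1](out)
        return self.head(out)

    # -- full passes -----------------------------------------------------------
    def forward(self, x) -> Tensor:
        """(N, C, H, W) image batch -> (N, K, H, W) logits."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        state = self.encode(x)
        vit_out = self.vit(state.bottleneck)
        return self.decode(state, vit_out)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """(H, W) or (N, C, H, W) image -> per-pixel class probabilities
        (K, H, W) or (N, K, H, W); each pixel's probabilities sum to 1."""
        arr = np.asarray(image, dtype=np.float32)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None, None]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits = self.forward(arr)
                probs = nn.softmax(logits, axis=1).data
        finally:
            if was_training:
                self.train()
        return probs[0] if squeeze else probs

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Argmax label map(s) for one (H, W) image or a batch."""
        probs = self.predict_proba(image)
        return np.argmax(probs, axis=-3).astype(np.uint8)


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Construct a model with deterministic parameter initialization."""
    return SegmentationModel(config, seed=seed)
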