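"""FAUnet: the frequency-aware noise-prediction U-Net.

The network operates in the packed wavelet domain: its input is the
channel-concatenation of the packed sub-bands of the current bridge state
X_t and of the conditional image, and its output is the predicted noise in
the same packed domain.  Three things distinguish it from a plain
diffusion U-Net:

* **Wavelet downsampling layers** replace strided convolution in the
  encoder: a feature map is split into its four Haar sub-bands
  (channel-packed, half resolution) and a learned 1×1 convolution projects
  the 4× channels onto the next pyramid's width.  A parallel shortcut maps
  the raw network input, Haar-decomposed to the matching resolution, onto
  each downsampled pyramid level and adds it in, keeping full-bandwidth
  information available deep in the encoder.
* **High-frequency supervision modules (HFSM)** in the decoder: a
  cross-attention block whose queries come from the summed detail bands
  (LH+HL+HH) of the conditional image at the matching resolution, and
  whose keys/values come from the decoder feature map.  Its output is
  concatenated with the skip connection as an extra decoder input.
* **Time embedding**: sinusoidal step embeddings, projected per ResBlock.

Setting ``use_wavelet_downsample=False`` and ``hfsm_levels=()`` yields the
stripped ablation variant with plain strided-convolution downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .wavelet import dwt_multilevel

__all__ = ["DenoiserConfig", "FAUnet"]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture description of the frequency-aware U-Net.

    ``in_channels`` counts the packed input: 4C sub-band channels for X_t
    plus 4C per conditional image (8C total for one condition source).
    ``out_channels`` is 4C (packed noise prediction).
    """

    levels: int = 2
    base_channels: int = 16
    channel_multipliers: tuple[int, ...] = (1, 2)
    attn_levels: tuple[int, ...] = ()          # extra per-level self-attention
    hfsm_levels: tuple[int, ...] = (1, 2)      # decoder levels with HFSM
    time_embed_dim: int = 64
    in_channels: int = 8
    out_channels: int = 4
    cond_channels: int = 1                     # raw conditional image channels
    use_wavelet_downsample: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.channel_multipliers) != self.levels:
            raise ValueError("need one channel multiplier per level")
        if any(m <= 0 for m in self.channel_multipliers):
            raise ValueError("channel multipliers must be positive")
        bad = set(self.attn_levels) | set(self.hfsm_levels)
        if not bad <= set(range(1, self.levels + 1)):
            raise ValueError(f"attn/hfsm levels must lie in 1..{self.levels}")
        if self.time_embed_dim % 2:
            raise ValueError("time_embed_dim must be even")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.channel_multipliers)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("channel_multipliers", "attn_levels", "hfsm_levels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        d = dict(d)
        for k in ("channel_multipliers", "attn_levels", "hfsm_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class ResBlock(nn.Module):
    """GroupNorm → SiLU → conv, with an additive time-embedding projection
    and a 1×1 skip when channel counts differ."""

    def __init__(self, cin: int, cout: int, temb_dim: int, rng: np.random.Generator):
        self.norm1 = nn.GroupNorm(cin)
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.temb_proj = nn.Linear(temb_dim, cout, rng)
        self.norm2 = nn.GroupNorm(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, zero_init=True)
        self.skip = nn.Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(nn.silu(self.norm1(x)))
        tproj = self.temb_proj(nn.silu(temb))
        n, c = tproj.shape
        h = h + tproj.reshape(n, c, 1, 1)
        h = self.conv2(nn.silu(self.norm2(h)))
        return h + (self.skip(x) if self.skip is not None else x)


class WaveletDownsample(nn.Module):
    """DWT → channel-packed sub-bands → learned 1×1 projection.

    Halves spatial dimensions, maps ``cin`` channels to ``target``.
    """

    def __init__(self, cin: int, target: int, rng: np.random.Generator):
        self.proj = nn.Conv2d(4 * cin, target, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        if h % 2 or w % 2:
            raise ValueError(f"wavelet downsampling needs even dims, got {h}x{w}")
        return self.proj(nn.haar_packed(x))


class StridedDownsample(nn.Module):
    """Plain stride-2 convolution (ablation baseline)."""

    def __init__(self, cin: int, target: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(cin, target, 3, rng, stride=2, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


class HFSM(nn.Module):
    """High-frequency feature supervision: cross-attention with queries
    from the conditional image's detail sub-bands.

    Q = Conv1×1(LH + HL + HH), K and V are independent 1×1 projections of
    the decoder feature map M; output is softmax(QKᵀ/√d_k)·V over flattened
    spatial positions, reshaped to M's geometry.
    """

    def __init__(self, cond_channels: int, feat_channels: int, rng: np.random.Generator):
        self.d_k = feat_channels
        self.q = nn.Conv2d(cond_channels, feat_channels, 1, rng)
        self.k = nn.Conv2d(feat_channels, feat_channels, 1, rng)
        self.v = nn.Conv2d(feat_channels, feat_channels, 1, rng)

    def __call__(self, m: Tensor, detail_sum: Tensor) -> Tensor:
        if m.shape[-2:] != detail_sum.shape[-2:]:
            raise ValueError(
                f"HFSM spatial mismatch: features {m.shape[-2:]} vs "
                f"conditional detail bands {detail_sum.shape[-2:]}"
            )
        n, c, h, w = m.shape
        q = self.q(detail_sum).reshape(n, c, h * w).transpose(0, 2, 1)
        k = self.k(m).reshape(n, c, h * w)
        v = self.v(m).reshape(n, c, h * w).transpose(0, 2, 1)
        attn = nn.softmax(nn.matmul(q, k) * (1.0 / np.sqrt(self.d_k)))
        out = nn.matmul(attn, v)
        return out.transpose(0, 2, 1).reshape(n, c, h, w)


class FAUnet(nn.Module):
    """Frequency-aware U-Net denoiser (see module docstring)."""

    def __init__(self, config: DenoiserConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        M = config.levels
        tdim = config.time_embed_dim

        self.temb_lin1 = nn.Linear(tdim, tdim, rng)
        self.temb_lin2 = nn.Linear(tdim, tdim, rng)

        self.stem = nn.Conv2d(config.in_channels, ch[0], 3, rng)
        self.enc_res = [ResBlock(ch[k], ch[k], tdim, rng) for k in range(M)]
        self.enc_attn = [
            nn.SelfAttention2d(ch[k], rng) if (k + 1) in config.attn_levels else None
            for k in range(M)
        ]
        if config.use_wavelet_downsample:
            self.down = [WaveletDownsample(ch[k], ch[k + 1], rng) for k in range(M - 1)]
            # raw-input shortcut: k-fold Haar of the packed input, projected
            self.raw_short = [
                nn.Conv2d(config.in_channels * 4 ** (k + 1), ch[k + 1], 1, rng,
                          zero_init=True)
                for k in range(M - 1)
            ]
        else:
            self.down = [StridedDownsample(ch[k], ch[k + 1], rng) for k in range(M - 1)]
            self.raw_short = []

        self.mid1 = ResBlock(ch[-1], ch[-1], tdim, rng)
        self.mid_attn = nn.SelfAttention2d(ch[-1], rng)
        self.mid2 = ResBlock(ch[-1], ch[-1], tdim, rng)

        self.hfsm = [
            HFSM(config.cond_channels, ch[k], rng)
            if (k + 1) in config.hfsm_levels else None
            for k in range(M)
        ]
        self.dec_res = []
        for k in range(M):
            cin = 2 * ch[k] + (ch[k] if self.hfsm[k] is not None else 0)
            self.dec_res.append(ResBlock(cin, ch[k], tdim, rng))
        self.up = [nn.Conv2d(ch[k], ch[k - 1], 3, rng) for k in range(1, M)]

        self.out_norm = nn.GroupNorm(ch[0])
        self.out_conv = nn.Conv2d(ch[0], config.out_channels, 3, rng, zero_init=True)

    # -- forward ----------------------------------------------------------

    def __call__(self, xt_packed, y_packed, cond_image, t) -> Tensor:
        return self.forward(xt_packed, y_packed, cond_image, t)

    def forward(self, xt_packed, y_packed, cond_image, t) -> Tensor:
        """Predict packed wavelet-domain noise.

        Parameters
        ----------
        xt_packed, y_packed:
            Packed sub-bands of X_t and of the conditional image, shape
            (N, 4C, H/2, W/2); must be spatially aligned.
        cond_image:
            Raw conditional image (N, C, H, W); feeds the HFSM path only.
        t:
            Integer step or per-sample array of steps.
        """
        xt_packed = xt_packed if isinstance(xt_packed, Tensor) else Tensor(xt_packed)
        y_packed = y_packed if isinstance(y_packed, Tensor) else Tensor(y_packed)
        if xt_packed.shape != y_packed.shape:
            raise ValueError(
                f"packed input shapes differ: {xt_packed.shape} vs {y_packed.shape}"
            )
        cond = np.asarray(cond_image.data if isinstance(cond_image, Tensor) else cond_image,
                          dtype=np.float64)
        cfg = self.config
        M = cfg.levels
        n = xt_packed.shape[0]

        t_arr = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.float64)), (n,))
        temb = Tensor(nn.sinusoidal_time_embedding(t_arr, cfg.time_embed_dim))
        temb = self.temb_lin2(nn.silu(self.temb_lin1(temb)))

        # conditional-image detail bands per level (no gradient flows here)
        details: list[Tensor | None] = [None] * M
        if any(h is not None for h in self.hfsm):
            stacks = dwt_multilevel(cond, M)
            for k in range(M):
                if self.hfsm[k] is not None:
                    s = stacks[k]
                    details[k] = Tensor(s.lh + s.hl + s.hh)

        x_in = nn.concat([xt_packed, y_packed], axis=1)
        h = self.stem(x_in)

        skips: list[Tensor] = []
        raw = x_in
        for k in range(M):
            h = self.enc_res[k](h, temb)
            if self.enc_attn[k] is not None:
                h = self.enc_attn[k](h)
            skips.append(h)
            if k < M - 1:
                h = self.down[k](h)
                if cfg.use_wavelet_downsample:
                    raw = nn.haar_packed(raw)
                    h = h + self.raw_short[k](raw)

        h = self.mid1(h, temb)
        h = self.mid_attn(h)
        h = self.mid2(h, temb)

        for k in range(M - 1, -1, -1):
            parts = [h, skips[k]]
            if self.hfsm[k] is not None:
                parts.append(self.hfsm[k](h, details[k]))
            h = self.dec_res[k](nn.concat(parts, axis=1), temb)
            if k > 0:
                h = self.up[k - 1](nn.upsample_nearest2(h))

        return self.out_conv(nn.silu(self.out_norm(h)))
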