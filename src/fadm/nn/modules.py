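"""Layers for the frequency-aware denoiser, built on :mod:`fadm.nn.tensor`.

Initialization is He-style truncated normal for convolution/linear weights
(zero-initialized where a residual branch should start as the identity);
every module draws its initial weights from an explicitly passed
``numpy.random.Generator``, so network construction is a pure function of
the seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d, matmul, silu, softmax

__all__ = ["Module", "Conv2d", "Linear", "GroupNorm", "SelfAttention2d",
           "sinusoidal_time_embedding"]


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    # truncate at 2 std: resample out-of-range draws
    w = rng.standard_normal(shape)
    bad = np.abs(w) > 2.0
    while bad.any():
        w[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(w) > 2.0
    return w * std


class Module:
    """Base class: recursive named-parameter collection and state dicts."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None,
                 zero_init: bool = False):
        k = kernel_size
        self.stride = stride
        self.padding = (k // 2) if padding is None else padding
        fan_in = in_channels * k * k
        if zero_init:
            w = np.zeros((out_channels, in_channels, k, k))
        else:
            w = _he_normal(rng, (out_channels, in_channels, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = _he_normal(rng, (in_features, out_features), in_features)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class GroupNorm(Module):
    """Group normalization over (N, C, H, W); groups chosen to divide C."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        while channels % groups:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.weight = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.bias = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        centred = xg - mu
        var = (centred * centred).mean(axis=2, keepdims=True)
        xhat = centred * (var + self.eps).pow_const(-0.5)
        return xhat.reshape(n, c, h, w) * self.weight + self.bias


class SelfAttention2d(Module):
    """Single-head spatial self-attention with residual output.

    Tokens are flattened spatial positions; the output projection is
    zero-initialized so the block starts as the identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.norm = GroupNorm(channels)
        self.q = Conv2d(channels, channels, 1, rng)
        self.k = Conv2d(channels, channels, 1, rng)
        self.v = Conv2d(channels, channels, 1, rng)
        self.proj = Conv2d(channels, channels, 1, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hn = self.norm(x)
        q = self.q(hn).reshape(n, c, h * w).transpose(0, 2, 1)
        k = self.k(hn).reshape(n, c, h * w)
        v = self.v(hn).reshape(n, c, h * w).transpose(0, 2, 1)
        attn = softmax(matmul(q, k) * (1.0 / np.sqrt(c)))
        out = matmul(attn, v).transpose(0, 2, 1).reshape(n, c, h, w)
        return x + self.proj(out)


def sinusoidal_time_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Classic sinusoidal embedding of integer time steps.

    Returns shape (len(t), dim); the first half holds sines, the second
    cosines, over geometrically spaced frequencies.
    """
    if dim % 2:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)
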