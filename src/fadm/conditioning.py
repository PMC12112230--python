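"""Pluggable providers of the conditional image.

The sampler is guided by a "conditional image": a one-shot, target-like
estimate computed once per sample from the source image.  At research
scale this is produced by a large pre-trained generative model; that is
deliberately kept behind an interface here so any callable can be slotted
in.  Two desk-scale providers ship with the package:

* :class:`IdentityProvider` — returns the source unchanged (ablation
  baseline: conditioning adds no target-specific information).
* :class:`RegressionProvider` — a small convolutional network fitted with
  a mean-absolute-error objective on the training split, giving a
  deterministic one-shot estimate of the target.  It is used purely as
  conditioning and never evaluated as the final output.

Whatever the provider, the bridge endpoints are untouched: X_T is always
the raw source image.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ConditionProvider", "IdentityProvider", "RegressionProvider",
           "get_provider", "PROVIDERS"]


class ConditionProvider:
    """Interface: map a source image (C, H, W) or batch (N, C, H, W) to a
    conditional image of identical shape with values in [−1, 1]."""

    name: str = "base"

    def provide(self, source: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, source: np.ndarray) -> np.ndarray:
        return self.provide(source)


class IdentityProvider(ConditionProvider):
    name = "identity"

    def provide(self, source: np.ndarray) -> np.ndarray:
        return np.asarray(source, dtype=np.float64)


class _SmallConvNet(nn.Module):
    def __init__(self, channels: int, hidden: int, rng: np.random.Generator):
        self.c1 = nn.Conv2d(channels, hidden, 3, rng)
        self.c2 = nn.Conv2d(hidden, hidden, 3, rng)
        self.c3 = nn.Conv2d(hidden, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.silu(self.c1(x))
        h = nn.silu(self.c2(h))
        return self.c3(h) + x  # residual: starts near the identity


class RegressionProvider(ConditionProvider):
    """One-shot source→target regressor used as conditioning.

    A three-layer residual convnet trained with an L1 objective; must be
    :meth:`fit` on the training split before use.
    """

    name = "regression"

    def __init__(self, channels: int = 1, hidden: int = 16, seed: int = 0):
        self.channels = channels
        self.net = _SmallConvNet(channels, hidden, np.random.default_rng(seed))
        self.fitted = False

    def fit(self, sources: np.ndarray, targets: np.ndarray, n_iters: int = 300,
            batch_size: int = 8, lr: float = 2e-3, seed: int = 0) -> list[float]:
        """Train on (N, C, H, W) paired arrays; returns the loss trace."""
        sources = np.asarray(sources, dtype=np.float64)
        targets = np.asarray(targets, dtype=np.float64)
        if sources.shape != targets.shape:
            raise ValueError(f"paired shapes differ: {sources.shape} vs {targets.shape}")
        rng = np.random.default_rng(seed)
        opt = nn.AdamW(self.net.parameters(), lr=lr, weight_decay=0.0)
        losses = []
        n = sources.shape[0]
        for _ in range(n_iters):
            idx = rng.integers(0, n, size=min(batch_size, n))
            pred = self.net(Tensor(sources[idx]))
            diff = pred - Tensor(targets[idx])
            # smooth |.| via sqrt(x^2 + eps): keeps the objective L1-like
            loss = ((diff * diff) + 1e-6).pow_const(0.5).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        self.fitted = True
        return losses

    def provide(self, source: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("RegressionProvider.provide called before fit()")
        source = np.asarray(source, dtype=np.float64)
        squeeze = source.ndim == 3
        if squeeze:
            source = source[None]
        out = self.net(Tensor(source)).data
        out = np.clip(out, -1.0, 1.0)
        return out[0] if squeeze else out


PROVIDERS = {
    IdentityProvider.name: IdentityProvider,
    RegressionProvider.name: RegressionProvider,
}


def get_provider(name: str, **kwargs) -> ConditionProvider:
    """Instantiate a registered provider by name."""
    if name not in PROVIDERS:
        raise KeyError(f"unknown provider {name!r}; have {sorted(PROVIDERS)}")
    return PROVIDERS[name](**kwargs)
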