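"""Image-quality metrics (PSNR, SSIM) and split-level evaluation reports.

Conventions: images are (C, H, W) on the [−1, 1] intensity scale, so the
default ``data_range`` is 2.  PSNR of identical images is reported as a
documented cap (``PSNR_CAP`` dB) instead of infinity.  SSIM uses the
universal defaults — Gaussian window of width 11 (σ = 1.5), stabilizers
K1 = 0.01, K2 = 0.03 — computed per channel and averaged; the filter
border (window radius) is cropped before averaging the local SSIM map.

A hook for distribution-level metrics (e.g. a pretrained-feature Fréchet
distance) is left as an optional column in the report format; nothing in
this package computes one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PSNR_CAP", "psnr", "ssim", "evaluate_split", "EvalReport"]

PSNR_CAP = 100.0  # dB reported when MSE == 0


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 2.0) -> float:
    """Peak signal-to-noise ratio, 10·log10(R²/MSE), in dB."""
    a, b = _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return min(10.0 * np.log10(data_range**2 / mse), PSNR_CAP)


def _ssim_single(x: np.ndarray, y: np.ndarray, data_range: float,
                 sigma: float = 1.5, truncate: float = 3.5,
                 k1: float = 0.01, k2: float = 0.03) -> float:
    win = 2 * int(truncate * sigma + 0.5) + 1  # 11 for the defaults
    if min(x.shape) < win:
        raise ValueError(f"image {x.shape} smaller than SSIM window {win}")
    filt = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(x, **filt)
    uy = gaussian_filter(y, **filt)
    uxx = gaussian_filter(x * x, **filt)
    uyy = gaussian_filter(y * y, **filt)
    uxy = gaussian_filter(x * y, **filt)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 2.0) -> float:
    """Mean local structural similarity; channels averaged for (C, H, W)."""
    a, b = _check_pair(a, b)
    if a.ndim == 2:
        return _ssim_single(a, b, data_range)
    if a.ndim != 3:
        raise ValueError(f"expected (H, W) or (C, H, W), got {a.shape}")
    return float(np.mean([_ssim_single(a[c], b[c], data_range)
                          for c in range(a.shape[0])]))


@dataclass(frozen=True)
class EvalReport:
    """Per-image PSNR/SSIM plus split-level mean ± standard deviation."""

    psnr_values: np.ndarray
    ssim_values: np.ndarray

    @property
    def psnr_mean(self) -> float:
        return float(self.psnr_values.mean())

    @property
    def psnr_std(self) -> float:
        return float(self.psnr_values.std())

    @property
    def ssim_mean(self) -> float:
        return float(self.ssim_values.mean())

    @property
    def ssim_std(self) -> float:
        return float(self.ssim_values.std())

    def to_text(self) -> str:
        lines = [
            "# image-quality report",
            "# data_range=2 ([-1,1] images); SSIM: gaussian window 11, sigma 1.5, "
            "K1=0.01, K2=0.03; PSNR cap %.0f dB; FID column reserved (n/a)" % PSNR_CAP,
            "index\tpsnr_db\tssim\tfid",
        ]
        for i, (p, s) in enumerate(zip(self.psnr_values, self.ssim_values)):
            lines.append(f"{i}\t{p:.4f}\t{s:.6f}\tn/a")
        lines.append(f"mean\t{self.psnr_mean:.4f}\t{self.ssim_mean:.6f}\tn/a")
        lines.append(f"std\t{self.psnr_std:.4f}\t{self.ssim_std:.6f}\tn/a")
        return "\n".join(lines) + "\n"


def evaluate_split(generated: list[np.ndarray], targets: list[np.ndarray],
                   data_range: float = 2.0) -> EvalReport:
    """Pairwise PSNR/SSIM over a split."""
    if len(generated) != len(targets):
        raise ValueError(f"list lengths differ: {len(generated)} vs {len(targets)}")
    if not generated:
        raise ValueError("empty evaluation lists")
    ps = np.array([psnr(g, t, data_range) for g, t in zip(generated, targets)])
    ss = np.array([ssim(g, t, data_range) for g, t in zip(generated, targets)])
    return EvalReport(psnr_values=ps, ssim_values=ss)
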