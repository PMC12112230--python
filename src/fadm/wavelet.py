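"""Orthonormal 2D Haar wavelet transform and sub-band channel packing.

One decomposition level splits an image into a low-frequency approximation
(LL) and three detail bands (LH, HL, HH), each at half the spatial
resolution.  The transform here is the *orthonormal* Haar filter bank
(taps ±1/√2), so it is an isometry: energy is conserved exactly and i.i.d.
Gaussian noise keeps its statistics across the transform — the property
that lets a diffusion model predict noise in the wavelet domain without a
change of scale.

Sign convention: the high-pass filter takes (first sample − second sample)
/ √2 along each axis.  LH carries vertical detail (high-pass along rows),
HL horizontal detail (high-pass along columns), HH diagonal detail.

Boundary handling: images must have even height and width at every level
used; odd sizes are rejected rather than padded, so no extension mode is
ever exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubbandStack",
    "dwt2",
    "idwt2",
    "dwt_multilevel",
    "idwt_multilevel",
    "pack_subbands",
    "unpack_subbands",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class SubbandStack:
    """The four sub-bands of one Haar decomposition level.

    Each band has shape ``(..., C, H/2, W/2)`` where the parent image had
    shape ``(..., C, H, W)``.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(
                f"sub-band shapes differ: ll {self.ll.shape}, lh {self.lh.shape}, "
                f"hl {self.hl.shape}, hh {self.hh.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape


def _check_even(h: int, w: int) -> None:
    if h % 2:
        raise ValueError(f"height {h} is odd; Haar DWT needs even spatial dims")
    if w % 2:
        raise ValueError(f"width {w} is odd; Haar DWT needs even spatial dims")


def dwt2(image: np.ndarray) -> SubbandStack:
    """Single-level orthonormal 2D Haar decomposition.

    Parameters
    ----------
    image:
        Array of shape ``(..., H, W)`` with even ``H`` and ``W``.  Leading
        axes (channels, batch) pass through untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[-2], image.shape[-1]
    _check_even(h, w)

    a = image[..., 0::2, :]
    b = image[..., 1::2, :]
    lo_r = (a + b) * _INV_SQRT2  # low-pass along rows (vertical pairing)
    hi_r = (a - b) * _INV_SQRT2

    ll = (lo_r[..., :, 0::2] + lo_r[..., :, 1::2]) * _INV_SQRT2
    hl = (lo_r[..., :, 0::2] - lo_r[..., :, 1::2]) * _INV_SQRT2
    lh = (hi_r[..., :, 0::2] + hi_r[..., :, 1::2]) * _INV_SQRT2
    hh = (hi_r[..., :, 0::2] - hi_r[..., :, 1::2]) * _INV_SQRT2
    return SubbandStack(ll=ll, lh=lh, hl=hl, hh=hh)


def idwt2(stack: SubbandStack) -> np.ndarray:
    """Exact inverse of :func:`dwt2` (up to float round-off)."""
    ll, lh, hl, hh = stack.ll, stack.lh, stack.hl, stack.hh
    lo_r = np.empty(ll.shape[:-1] + (2 * ll.shape[-1],), dtype=np.float64)
    hi_r = np.empty_like(lo_r)
    lo_r[..., 0::2] = (ll + hl) * _INV_SQRT2
    lo_r[..., 1::2] = (ll - hl) * _INV_SQRT2
    hi_r[..., 0::2] = (lh + hh) * _INV_SQRT2
    hi_r[..., 1::2] = (lh - hh) * _INV_SQRT2

    out = np.empty(lo_r.shape[:-2] + (2 * lo_r.shape[-2], lo_r.shape[-1]))
    out[..., 0::2, :] = (lo_r + hi_r) * _INV_SQRT2
    out[..., 1::2, :] = (lo_r - hi_r) * _INV_SQRT2
    return out


def max_depth(h: int, w: int) -> int:
    """Largest decomposition depth supported by an H×W image."""
    d = 0
    while h % 2 == 0 and w % 2 == 0 and h >= 2 and w >= 2:
        h //= 2
        w //= 2
        d += 1
    return d


def dwt_multilevel(image: np.ndarray, levels: int) -> list[SubbandStack]:
    """Multi-level decomposition: level k+1 decomposes level k's LL band.

    Returns one :class:`SubbandStack` per level, coarse bands last; the
    level-k bands have spatial shape ``(H/2^k, W/2^k)``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[-2], image.shape[-1]
    feasible = max_depth(h, w)
    if levels > feasible:
        raise ValueError(
            f"image of size {h}x{w} supports at most {feasible} decomposition "
            f"level(s); {levels} requested"
        )
    stacks: list[SubbandStack] = []
    current = image
    for _ in range(levels):
        s = dwt2(current)
        stacks.append(s)
        current = s.ll
    return stacks


def idwt_multilevel(stacks: list[SubbandStack]) -> np.ndarray:
    """Inverse of :func:`dwt_multilevel` (coarsest stack last)."""
    if not stacks:
        raise ValueError("empty stack list")
    current = stacks[-1].ll
    for s in reversed(stacks):
        s = SubbandStack(ll=current, lh=s.lh, hl=s.hl, hh=s.hh)
        current = idwt2(s)
    return current


def pack_subbands(stack: SubbandStack) -> np.ndarray:
    """Stack the four sub-bands along the channel axis.

    Input bands of shape ``(C, H/2, W/2)`` (or with a leading batch axis)
    give an output of shape ``(4C, H/2, W/2)``; channel order is frozen as
    (ll, lh, hl, hh) blocks.
    """
    return np.concatenate([stack.ll, stack.lh, stack.hl, stack.hh], axis=-3)


def unpack_subbands(packed: np.ndarray) -> SubbandStack:
    """Exact inverse of :func:`pack_subbands`."""
    packed = np.asarray(packed)
    c4 = packed.shape[-3]
    if c4 % 4:
        raise ValueError(f"packed channel count {c4} is not a multiple of 4")
    ll, lh, hl, hh = np.split(packed, 4, axis=-3)
    return SubbandStack(ll=ll, lh=lh, hl=hl, hh=hh)
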