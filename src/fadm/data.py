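"""Paired synthetic phantoms and real-volume slice extraction.

The default test bed is a head-phantom generator emulating co-registered
paired acquisitions of the same anatomy under two different contrasts
(e.g. two field strengths or two pulse sequences): each pair shares one
set of tissue masks — an outer head ellipse, K inner tissue ellipses and
optionally one small focal lesion — rendered through two distinct
per-tissue contrast lookup tables, with independent additive Gaussian
noise per image.  Everything is a pure function of the seed.

For user-supplied data, co-registered 3D volumes in NIfTI format can be
sliced along any anatomical plane, optionally stacking each slice with its
two neighbours as channels to inject 3D context into a 2D model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomParams", "PhantomPair", "SliceRecord", "DatasetSplits",
    "make_phantom_pair", "make_dataset", "render_masks", "load_volume_slices",
    "pairs_to_arrays",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for paired phantoms.

    Contrast tables list intensities (on the [−1, 1] scale) for
    (head tissue, inner tissue 1..K, lesion); the background is −1 in both
    modalities.  The default tables differ strongly between modalities so
    the translation task is non-trivial relative to the noise floor.
    """

    n_tissues: int = 3
    noise_sigma: float = 0.02
    lesion_fraction: float = 0.5
    source_contrast: tuple[float, ...] = (0.0, 0.35, -0.35, 0.15, 0.25)
    target_contrast: tuple[float, ...] = (0.45, -0.15, 0.30, -0.30, 0.85)
    jitter: float = 0.03   # relative geometry jitter between a subject's slices

    def __post_init__(self) -> None:
        if len(self.source_contrast) != self.n_tissues + 2:
            raise ValueError("source_contrast needs n_tissues + 2 entries")
        if len(self.target_contrast) != self.n_tissues + 2:
            raise ValueError("target_contrast needs n_tissues + 2 entries")


@dataclass(frozen=True)
class PhantomPair:
    """A co-registered (source, target) image pair; shapes (1, H, W)."""

    source: np.ndarray
    target: np.ndarray
    seed: int
    subject_id: int
    meta: dict


@dataclass(frozen=True)
class SliceRecord:
    image: np.ndarray          # (1, H, W) or (3, H, W) when stacked
    subject_id: str
    plane: str
    index: int


@dataclass(frozen=True)
class DatasetSplits:
    train: list[PhantomPair]
    val: list[PhantomPair]
    test: list[PhantomPair]
    subjects: dict[str, list[int]] = field(default_factory=dict)


# -- geometry ---------------------------------------------------------------


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return u * u + v * v <= 1.0


def _draw_geometry(rng: np.random.Generator, size: int, params: PhantomParams,
                   lesion: bool) -> dict:
    c = size / 2.0
    geom: dict = {
        "size": size,
        "head": [c + rng.uniform(-0.02, 0.02) * size,
                 c + rng.uniform(-0.02, 0.02) * size,
                 rng.uniform(0.36, 0.44) * size,
                 rng.uniform(0.40, 0.47) * size,
                 rng.uniform(-0.3, 0.3)],
        "tissues": [],
        "lesion": None,
    }
    for _ in range(params.n_tissues):
        geom["tissues"].append([
            c + rng.uniform(-0.18, 0.18) * size,
            c + rng.uniform(-0.2, 0.2) * size,
            rng.uniform(0.08, 0.2) * size,
            rng.uniform(0.08, 0.2) * size,
            rng.uniform(-np.pi, np.pi),
        ])
    if lesion:
        geom["lesion"] = [
            c + rng.uniform(-0.15, 0.15) * size,
            c + rng.uniform(-0.18, 0.18) * size,
            rng.uniform(0.05, 0.1) * size,
            rng.uniform(0.05, 0.1) * size,
            rng.uniform(-np.pi, np.pi),
        ]
    return geom


def _jitter_geometry(geom: dict, rng: np.random.Generator, rel: float) -> dict:
    def jit(e):
        return [v + rng.normal(0.0, rel * geom["size"] * 0.5) if i < 4 else
                v + rng.normal(0.0, rel) for i, v in enumerate(e)]

    out = {"size": geom["size"], "head": jit(geom["head"]),
           "tissues": [jit(e) for e in geom["tissues"]],
           "lesion": jit(geom["lesion"]) if geom["lesion"] is not None else None}
    return out


def render_masks(geom: dict) -> np.ndarray:
    """Label map from stored geometry: 0 background, 1 head tissue,
    2..K+1 inner tissues, K+2 lesion.  Later regions paint over earlier."""
    size = geom["size"]
    labels = np.zeros((size, size), dtype=np.int64)
    head = _ellipse_mask(size, *geom["head"])
    labels[head] = 1
    for i, e in enumerate(geom["tissues"]):
        m = _ellipse_mask(size, *e) & head
        labels[m] = 2 + i
    if geom["lesion"] is not None:
        m = _ellipse_mask(size, *geom["lesion"]) & head
        labels[m] = 2 + len(geom["tissues"])
    return labels


def _render_pair(geom: dict, params: PhantomParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    labels = render_masks(geom)
    k = len(geom["tissues"])
    src_lut = np.array([-1.0, params.source_contrast[0],
                        *params.source_contrast[1:1 + k], params.source_contrast[-1]])
    tgt_lut = np.array([-1.0, params.target_contrast[0],
                        *params.target_contrast[1:1 + k], params.target_contrast[-1]])
    source = src_lut[labels]
    target = tgt_lut[labels]
    if params.noise_sigma > 0:
        source = source + rng.normal(0.0, params.noise_sigma, source.shape)
        target = target + rng.normal(0.0, params.noise_sigma, target.shape)
    source = np.clip(source, -1.0, 1.0)[None]
    target = np.clip(target, -1.0, 1.0)[None]
    return source, target


# -- public generators ------------------------------------------------------


def make_phantom_pair(seed: int, size: int = 32,
                      params: PhantomParams | None = None,
                      force_lesion: bool | None = None) -> PhantomPair:
    """One reproducible paired phantom.

    ``size`` must be even and at least 16 (wavelet stages need even dims).
    """
    if size % 2 or size < 16:
        raise ValueError(f"size must be even and >= 16, got {size}")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    lesion = (rng.random() < params.lesion_fraction
              if force_lesion is None else force_lesion)
    geom = _draw_geometry(rng, size, params, lesion)
    source, target = _render_pair(geom, params, rng)
    meta = {"geometry": geom, "noise_sigma": params.noise_sigma, "lesion": lesion}
    return PhantomPair(source=source, target=target, seed=seed, subject_id=-1,
                       meta=meta)


def make_dataset(n_subjects: int, slices_per_subject: int, seed: int,
                 size: int = 32, params: PhantomParams | None = None) -> DatasetSplits:
    """Subject-independent 80/10/10 train/val/test splits.

    Each subject has its own tissue geometry; its slices share that
    geometry up to a small jitter, emulating adjacent slices of one
    volume.  Subjects, not slices, are assigned to splits, so no anatomy
    leaks across them.
    """
    if n_subjects < 10:
        raise ValueError(f"need >= 10 subjects for an 80/10/10 split, got {n_subjects}")
    params = params or PhantomParams()
    root = np.random.default_rng(seed)
    n_val = max(1, round(0.1 * n_subjects))
    n_test = max(1, round(0.1 * n_subjects))
    n_train = n_subjects - n_val - n_test
    order = root.permutation(n_subjects)
    assign = {}
    for i, sid in enumerate(order):
        assign[int(sid)] = ("train" if i < n_train
                            else "val" if i < n_train + n_val else "test")

    splits: dict[str, list[PhantomPair]] = {"train": [], "val": [], "test": []}
    subjects: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for sid in range(n_subjects):
        sub_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        lesion = bool(sub_rng.random() < params.lesion_fraction)
        base = _draw_geometry(sub_rng, size, params, lesion)
        subjects[assign[sid]].append(sid)
        for sl in range(slices_per_subject):
            geom = _jitter_geometry(base, sub_rng, params.jitter)
            source, target = _render_pair(geom, params, sub_rng)
            meta = {"geometry": geom, "noise_sigma": params.noise_sigma,
                    "lesion": lesion, "slice": sl}
            splits[assign[sid]].append(PhantomPair(
                source=source, target=target, seed=seed, subject_id=sid, meta=meta))
    return DatasetSplits(train=splits["train"], val=splits["val"],
                         test=splits["test"], subjects=subjects)


def pairs_to_arrays(pairs: list[PhantomPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a pair list into (N, C, H, W) source and target arrays."""
    return (np.stack([p.source for p in pairs]),
            np.stack([p.target for p in pairs]))


# -- real volumes -----------------------------------------------------------

_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


def load_volume_slices(path, plane: str = "axial", stack_adjacent: bool = False,
                       size: int = 256, subject_id: str | None = None) -> list[SliceRecord]:
    """Extract normalized 2D slices from a co-registered NIfTI volume.

    Intensities are rescaled per volume (min–max) to [−1, 1]; slices are
    resized to ``size``×``size``.  With ``stack_adjacent`` each record has
    3 channels: slices (index−1, index, index+1), edge slices replicating
    their single neighbour.
    """
    import nibabel as nib
    from skimage.transform import resize

    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}, got {plane!r}")
    try:
        vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    except Exception as e:  # unreadable file
        raise IOError(f"could not read NIfTI volume {path}: {e}") from e
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")

    lo, hi = vol.min(), vol.max()
    vol = (2.0 * (vol - lo) / (hi - lo) - 1.0) if hi > lo else np.zeros_like(vol)
    axis = _PLANE_AXIS[plane]
    vol = np.moveaxis(vol, axis, 0)  # (D, A, B)
    depth = vol.shape[0]
    sid = subject_id if subject_id is not None else str(path)

    records = []
    resized = np.stack([
        resize(vol[i], (size, size), anti_aliasing=True, preserve_range=True)
        for i in range(depth)
    ])
    resized = np.clip(resized, -1.0, 1.0)
    for i in range(depth):
        if stack_adjacent:
            img = np.stack([resized[max(i - 1, 0)], resized[i],
                            resized[min(i + 1, depth - 1)]])
        else:
            img = resized[i][None]
        records.append(SliceRecord(image=img, subject_id=sid, plane=plane, index=i))
    return records
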