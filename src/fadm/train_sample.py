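"""Training loop and iterative sampler for the frequency-aware bridge.

Training draws a random step t, forms X_t from the analytic bridge
posterior between a paired (target, source) image couple, and regresses
the packed wavelet-domain noise ε = (X_t − X_0)/σ_t with a mean-squared
objective.  Because the Haar transform is orthonormal, the wavelet-domain
MSE equals the pixel-domain MSE exactly; the network simply never leaves
the packed domain.

Sampling starts from the source image (X_T), and per step: decompose the
current state and the conditional image (DWT + channel packing), run the
denoiser, bring the predicted noise back to pixel space (unpack + inverse
DWT), and take one ancestral reverse step.  The step grid may be a
uniform-stride subset of the training steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import bridge, wavelet
from .conditioning import ConditionProvider
from .faunet import DenoiserConfig, FAUnet
from .nn import AdamW, Tensor

__all__ = ["TrainConfig", "TrainResult", "training_step", "sample",
           "checkpoint_select", "train", "save_checkpoint", "load_checkpoint",
           "desk_train_config"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Full-scale defaults follow common practice for bridge diffusion on
    256×256 MRI slices (learning rate 5e−5, batch 2, T = 1000);
    :func:`desk_train_config` returns the desk-scale preset used by the
    synthetic test bed (32×32, T = 20, a larger learning rate suited to
    the much smaller network and shorter schedule).
    """

    learning_rate: float = 5e-5
    batch_size: int = 2
    n_steps: int = 1000
    beta_shape: str = "symmetric_triangular"
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    max_iterations: int = 100_000
    validation_interval: int = 1000
    n_infer_steps: int | None = None
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_steps < 2:
            raise ValueError("learning_rate, batch_size and n_steps must be positive")


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale preset: 32×32 phantoms, T=20, ~2000 iterations on one CPU."""
    base = dict(learning_rate=1e-3, batch_size=2, n_steps=20,
                max_iterations=2000, validation_interval=250, seed=0)
    base.update(overrides)
    return TrainConfig(**base)


def _packed(x: np.ndarray) -> np.ndarray:
    return wavelet.pack_subbands(wavelet.dwt2(x))


def _unpacked(x: np.ndarray) -> np.ndarray:
    return wavelet.idwt2(wavelet.unpack_subbands(x))


def training_step(batch_src: np.ndarray, batch_tgt: np.ndarray,
                  provider: ConditionProvider, net: FAUnet,
                  sched: bridge.NoiseSchedule, opt: AdamW | None,
                  rng: np.random.Generator) -> float:
    """One stochastic gradient step; returns the (finite) scalar loss.

    ``opt=None`` evaluates the loss without updating parameters (used for
    validation).
    """
    n = batch_src.shape[0]
    x0 = np.asarray(batch_tgt, dtype=np.float64)   # clean target = time 0
    xT = np.asarray(batch_src, dtype=np.float64)   # source = time T
    t = rng.integers(1, sched.n_steps + 1, size=n)

    s2 = sched.sigma2_fwd[t][:, None, None, None]
    sb2 = sched.sigma2_bwd[t][:, None, None, None]
    tot = s2 + sb2
    mu = (sb2 * x0 + s2 * xT) / tot
    var = s2 * sb2 / tot
    xt = mu + np.sqrt(var) * rng.standard_normal(x0.shape)
    eps = (xt - x0) / np.sqrt(s2)

    cond = provider(xT)
    pred = net(_packed(xt), _packed(cond), cond, t)
    diff = pred - Tensor(_packed(eps))
    loss = (diff * diff).mean()
    val = float(loss.data)
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite training loss (t={t.tolist()}, batch size {n})"
        )
    if opt is not None:
        opt.zero_grad()
        net.zero_grad()
        loss.backward()
        opt.step()
    return val


def _infer_times(n_steps: int, n_infer: int | None) -> np.ndarray:
    """Descending step grid T = t_0 > t_1 > … > 0 (uniform stride subset)."""
    if n_infer is None or n_infer >= n_steps:
        return np.arange(n_steps, -1, -1)
    if n_infer < 1:
        raise ValueError("n_infer_steps must be >= 1")
    return np.unique(np.round(np.linspace(0, n_steps, n_infer + 1)).astype(int))[::-1]


def sample(source: np.ndarray, provider: ConditionProvider, net,
           sched: bridge.NoiseSchedule, rng: np.random.Generator,
           n_infer_steps: int | None = None) -> np.ndarray:
    """Translate source → target estimate by iterative reverse sampling.

    ``net`` is any callable ``(xt_packed, y_packed, cond_image, t) →``
    packed noise prediction (a trained :class:`FAUnet`, or an oracle in
    tests).  Accepts a single (C, H, W) image or an (N, C, H, W) batch.
    """
    src = np.asarray(source, dtype=np.float64)
    squeeze = src.ndim == 3
    if squeeze:
        src = src[None]
    cond = provider(src)
    y_packed = _packed(cond)

    x = src.copy()
    times = _infer_times(sched.n_steps, n_infer_steps)
    for t_hi, t_lo in zip(times[:-1], times[1:]):
        pred = net(_packed(x), y_packed, cond, int(t_hi))
        eps_hat = _unpacked(pred.data if isinstance(pred, Tensor) else np.asarray(pred))
        x = bridge.reverse_step(x, eps_hat, int(t_hi), int(t_lo), sched, rng)
    x = np.clip(x, -1.0, 1.0)
    return x[0] if squeeze else x


def checkpoint_select(val_losses: list[float]) -> int:
    """Index of the minimum validation loss; ties go to the later entry."""
    if not val_losses:
        raise ValueError("empty validation history")
    arr = np.asarray(val_losses, dtype=np.float64)
    best = arr.min()
    return int(np.flatnonzero(arr == best)[-1])


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path, net: FAUnet, train_cfg: TrainConfig,
                    sched: bridge.NoiseSchedule, iteration: int,
                    rng_state: dict | None = None) -> None:
    """Parameter tree + configs + schedule in one .npz archive."""
    meta = {
        "denoiser_config": net.config.to_dict(),
        "train_config": asdict(train_cfg),
        "iteration": iteration,
        "rng_state": repr(rng_state) if rng_state is not None else None,
    }
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    arrays["schedule/beta"] = sched.beta
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[FAUnet, TrainConfig, bridge.NoiseSchedule, int]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        beta = z["schedule/beta"]
    net = FAUnet(DenoiserConfig.from_dict(meta["denoiser_config"]))
    net.load_state_dict(params)
    tc_raw = dict(meta["train_config"])
    tc_raw["betas"] = tuple(tc_raw["betas"])
    tcfg = TrainConfig(**tc_raw)
    sigma2_fwd = np.concatenate([[0.0], np.cumsum(beta)])
    sched = bridge.NoiseSchedule(n_steps=len(beta), beta=beta,
                                 sigma2_fwd=sigma2_fwd,
                                 sigma2_bwd=sigma2_fwd[-1] - sigma2_fwd)
    return net, tcfg, sched, int(meta["iteration"])


# -- orchestration ----------------------------------------------------------


@dataclass
class TrainResult:
    net: FAUnet
    sched: bridge.NoiseSchedule
    train_losses: list[float]
    val_history: list[tuple[int, float]]   # (iteration, val loss)
    best_index: int
    log_lines: list[str] = field(default_factory=list)

    @property
    def best_iteration(self) -> int:
        return self.val_history[self.best_index][0]


def train(train_cfg: TrainConfig, denoiser_cfg: DenoiserConfig,
          train_pairs: tuple[np.ndarray, np.ndarray],
          val_pairs: tuple[np.ndarray, np.ndarray],
          provider: ConditionProvider,
          log_path=None, verbose: bool = False) -> TrainResult:
    """Full training run; keeps the checkpoint with minimum validation loss.

    ``train_pairs``/``val_pairs`` are (sources, targets) arrays of shape
    (N, C, H, W).  All randomness flows from ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    sched = bridge.make_schedule(train_cfg.n_steps, shape=train_cfg.beta_shape)
    net = FAUnet(denoiser_cfg, seed=int(rng.integers(0, 2**31 - 1)))
    opt = AdamW(net.parameters(), lr=train_cfg.learning_rate,
                betas=train_cfg.betas, weight_decay=train_cfg.weight_decay)

    src, tgt = train_pairs
    n = src.shape[0]
    losses: list[float] = []
    val_history: list[tuple[int, float]] = []
    best_states: list[dict] = []
    log_lines = ["iteration\ttrain_loss\tval_loss"]

    def validate(it: int) -> None:
        vrng = np.random.default_rng(10_000 + train_cfg.seed)  # fixed for comparability
        vsrc, vtgt = val_pairs
        vloss = float(np.mean([
            training_step(vsrc[i:i + train_cfg.batch_size],
                          vtgt[i:i + train_cfg.batch_size],
                          provider, net, sched, None, vrng)
            for i in range(0, vsrc.shape[0], train_cfg.batch_size)
        ]))
        val_history.append((it, vloss))
        best_states.append(net.state_dict())
        recent = float(np.mean(losses[-train_cfg.validation_interval:])) if losses else float("nan")
        line = f"{it}\t{recent:.6f}\t{vloss:.6f}"
        log_lines.append(line)
        if verbose:
            import sys
            print(line, file=sys.stderr)

    for it in range(1, train_cfg.max_iterations + 1):
        idx = rng.integers(0, n, size=train_cfg.batch_size)
        losses.append(training_step(src[idx], tgt[idx], provider, net, sched, opt, rng))
        if it % train_cfg.validation_interval == 0 or it == train_cfg.max_iterations:
            validate(it)

    best = checkpoint_select([v for _, v in val_history])
    net.load_state_dict(best_states[best])

    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    if train_cfg.checkpoint_dir is not None:
        ckdir = Path(train_cfg.checkpoint_dir)
        ckdir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(ckdir / "best.npz", net, train_cfg, sched,
                        val_history[best][0])
    return TrainResult(net=net, sched=sched, train_losses=losses,
                       val_history=val_history, best_index=best,
                       log_lines=log_lines)
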