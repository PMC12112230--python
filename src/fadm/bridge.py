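"""Analytic paired Schrödinger-bridge posterior and ancestral sampling.

For a paired bridge pinned at a clean target image ``x0`` (time 0) and a
source image ``xT`` (time T), the marginal at an intermediate step t is
Gaussian:

    q(X_t | x0, xT) = N( mu_t, var_t * I )
    mu_t  = (sbar_t² * x0 + s_t² * xT) / (sbar_t² + s_t²)
    var_t = s_t² * sbar_t² / (sbar_t² + s_t²)

where s_t² is the noise variance accumulated from time 0 up to t and
sbar_t² the variance accumulated from t up to T.  The mean interpolates
the endpoints; the variance vanishes at both boundaries and peaks inside.

Discrete-time convention: β is a length-T array of per-step variance
increments, so s_t² = Σ_{u<t} β_u and sbar_t² = Σ_{u>=t} β_u; both
accumulated arrays have length T+1 and satisfy s_t² + sbar_t² = s_T² for
every t.

The denoiser is trained to regress the standardized displacement
ε = (x_t − x0)/s_t (ε-prediction); the reverse ancestral step forms
x̂0 = x_t − s_t ε̂ and samples the same posterior restricted to the
sub-interval [0, t], evaluated at the previous step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "posterior_params",
    "sample_xt",
    "epsilon_target",
    "reverse_step",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step β values and both accumulated variances of the bridge.

    Attributes
    ----------
    n_steps:
        T, the number of diffusion steps.
    beta:
        shape (T,), per-step variance increments β_t > 0.
    sigma2_fwd:
        shape (T+1,), s_t² accumulated from time 0; ``sigma2_fwd[0] == 0``.
    sigma2_bwd:
        shape (T+1,), sbar_t² accumulated from time T; ``sigma2_bwd[T] == 0``.
    """

    n_steps: int
    beta: np.ndarray
    sigma2_fwd: np.ndarray
    sigma2_bwd: np.ndarray

    @property
    def total_var(self) -> float:
        """s_T², the total accumulated variance of the bridge."""
        return float(self.sigma2_fwd[-1])

    def sigma(self, t: int) -> float:
        """s_t, the forward accumulated standard deviation at step t."""
        return float(np.sqrt(self.sigma2_fwd[t]))


def make_schedule(
    n_steps: int,
    beta_peak: float | None = None,
    shape: str = "symmetric_triangular",
) -> NoiseSchedule:
    """Build a noise schedule.

    Parameters
    ----------
    n_steps:
        Number of diffusion steps T (>= 2).
    beta_peak:
        Maximum per-step β.  Default scales the schedule so the total
        accumulated variance s_T² is 1 on the normalized intensity scale
        (2/T for the triangular shape, 1/T for the constant one).
    shape:
        ``"symmetric_triangular"`` — β rises linearly to the midpoint then
        falls symmetrically (the usual bridge convention, concentrating
        noise mid-trajectory); ``"constant"`` — flat β, handy for analytic
        tests.
    """
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    if shape == "constant":
        if beta_peak is None:
            beta_peak = 1.0 / n_steps
        if beta_peak <= 0:
            raise ValueError(f"beta_peak must be positive, got {beta_peak}")
        beta = np.full(n_steps, float(beta_peak))
    elif shape == "symmetric_triangular":
        if beta_peak is None:
            beta_peak = 2.0 / n_steps
        if beta_peak <= 0:
            raise ValueError(f"beta_peak must be positive, got {beta_peak}")
        # symmetric around the midpoint of [0, T]: evaluate the triangle at
        # step centres so beta[t] == beta[T-1-t] exactly
        centres = (np.arange(n_steps) + 0.5) / n_steps  # in (0, 1)
        tri = 1.0 - np.abs(2.0 * centres - 1.0)
        beta = float(beta_peak) * tri
    else:
        raise ValueError(f"unknown schedule shape: {shape!r}")

    sigma2_fwd = np.concatenate([[0.0], np.cumsum(beta)])
    sigma2_bwd = sigma2_fwd[-1] - sigma2_fwd
    return NoiseSchedule(
        n_steps=n_steps, beta=beta, sigma2_fwd=sigma2_fwd, sigma2_bwd=sigma2_bwd
    )


def _check_t(t: int, sched: NoiseSchedule) -> None:
    if not 0 <= t <= sched.n_steps:
        raise IndexError(f"t={t} outside [0, {sched.n_steps}]")


def posterior_params(
    x0: np.ndarray, xT: np.ndarray, t: int, sched: NoiseSchedule
) -> tuple[np.ndarray, float]:
    """Mean and (scalar, isotropic) variance of q(X_t | x0, xT)."""
    _check_t(t, sched)
    x0 = np.asarray(x0, dtype=np.float64)
    xT = np.asarray(xT, dtype=np.float64)
    if x0.shape != xT.shape:
        raise ValueError(f"endpoint shapes differ: {x0.shape} vs {xT.shape}")
    s2 = sched.sigma2_fwd[t]
    sb2 = sched.sigma2_bwd[t]
    tot = s2 + sb2
    mu = (sb2 * x0 + s2 * xT) / tot
    var = float(s2 * sb2 / tot)
    return mu, var


def sample_xt(
    x0: np.ndarray,
    xT: np.ndarray,
    t: int,
    sched: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw X_t ~ q(X_t | x0, xT); exact endpoints at t=0 and t=T."""
    mu, var = posterior_params(x0, xT, t, sched)
    if var == 0.0:
        return mu
    return mu + np.sqrt(var) * rng.standard_normal(mu.shape)


def epsilon_target(
    x0: np.ndarray, xt: np.ndarray, t: int, sched: NoiseSchedule
) -> np.ndarray:
    """The regression target ε = (x_t − x0) / s_t for the denoiser."""
    _check_t(t, sched)
    if t == 0:
        raise ValueError("epsilon target undefined at t=0 (s_0 = 0)")
    return (np.asarray(xt, dtype=np.float64) - np.asarray(x0, dtype=np.float64)) / (
        sched.sigma(t)
    )


def reverse_step(
    xt: np.ndarray,
    eps_hat: np.ndarray,
    t: int,
    t_prev: int,
    sched: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """One ancestral step of the reverse bridge, from step t to t_prev < t.

    Forms the clean-image estimate x̂0 = x_t − s_t ε̂ and samples the
    analytic posterior of the sub-bridge pinned at (x̂0 at time 0, x_t at
    time t), evaluated at t_prev.  When ``t_prev == 0`` the step is
    deterministic and returns x̂0.
    """
    _check_t(t, sched)
    if not 0 <= t_prev < t:
        raise ValueError(f"need 0 <= t_prev < t, got t_prev={t_prev}, t={t}")
    xt = np.asarray(xt, dtype=np.float64)
    x0_hat = xt - sched.sigma(t) * np.asarray(eps_hat, dtype=np.float64)
    if t_prev == 0:
        return x0_hat
    s2 = sched.sigma2_fwd[t_prev]                       # accumulated on [0, t_prev]
    sb2 = sched.sigma2_fwd[t] - sched.sigma2_fwd[t_prev]  # accumulated on [t_prev, t]
    tot = s2 + sb2
    mu = (sb2 * x0_hat + s2 * xt) / tot
    var = s2 * sb2 / tot
    return mu + np.sqrt(var) * rng.standard_normal(mu.shape)
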