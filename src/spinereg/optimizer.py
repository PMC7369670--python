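"""Adaptive stochastic gradient descent (ASGD) and stochastic voxel sampling.

Each iteration draws a fresh uniform random subset of fixed-image positions,
evaluates the cost gradient on it, and takes a step

    mu <- mu - gamma(t_k) * g_k / scales,    gamma(t) = a / (t + A)^alpha.

The internal "time" t adapts to the observed gradient sequence: when
successive stochastic gradients point in conflicting directions (oscillation,
a sign the step is too large) t is advanced, shrinking the step; when they
agree, t is reduced (floored at 0), keeping the step large while steady
progress is being made.  The step scale ``a`` can be estimated automatically
from a short gradient-magnitude probe at the starting point so that the first
step moves the parameters by a prescribed amount.

A plain deterministic gradient-descent fallback with dense sampling is
provided for exercising the metric layer without stochastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import Volume

__all__ = ["ASGDConfig", "SamplerConfig", "asgd_minimize", "draw_samples",
           "gradient_descent"]


@dataclass
class ASGDConfig:
    """Hyperparameters of the adaptive step-size rule.

    ``a=None`` triggers automatic estimation: ``a`` is set so the first
    update's largest parameter change equals ``init_step`` (parameter units;
    mm for translations and control-point displacements).
    """

    max_iterations: int = 500
    a: float | None = None
    A: float = 20.0
    alpha: float = 1.0
    init_step: float = 1.0
    max_step: float | None = None  # cap on per-iteration parameter change
    average_tail: float = 0.5  # fraction of final iterates averaged into mu
    f_max: float = 1.0
    f_min: float = -0.5
    omega: float = 0.2
    n_probe: int = 5

    def __post_init__(self) -> None:
        if self.A <= 0 or not (0 < self.alpha <= 1):
            raise ValueError("require A > 0 and 0 < alpha <= 1")
        if not (0.0 <= self.average_tail <= 1.0):
            raise ValueError("average_tail must lie in [0, 1]")


@dataclass
class SamplerConfig:
    """Uniform random sampling over the fixed-image domain."""

    n_samples: int = 2048
    seed: int = 0
    mask: np.ndarray | None = None  # boolean voxel mask, same shape as volume

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def draw_samples(volume: Volume, cfg: SamplerConfig, iteration: int) -> np.ndarray:
    """Fresh uniform positions (N, 3) in physical mm, deterministic given
    (seed, iteration).

    Positions are continuous: a random voxel (restricted to the mask if one is
    given) jittered uniformly within its cell, which keeps samples off the
    exact grid points where the interpolant's gradient is undefined.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, iteration]))
    shape = np.array(volume.shape)
    if cfg.mask is not None:
        flat = np.flatnonzero(cfg.mask)
        if flat.size == 0:
            raise ValueError("empty sampling domain: mask has no voxels")
        pick = rng.choice(flat, size=cfg.n_samples)
        vox = np.stack(np.unravel_index(pick, tuple(shape)), axis=1).astype(float)
        idx = vox + rng.uniform(-0.5, 0.5, size=(cfg.n_samples, 3))
        idx = np.clip(idx, 0, shape - 1)
    else:
        idx = rng.uniform(0, 1, size=(cfg.n_samples, 3)) * (shape - 1)
    return volume.voxel_to_physical(idx)


def _sigmoid_advance(x: float, cfg: ASGDConfig) -> float:
    return cfg.f_min + (cfg.f_max - cfg.f_min) / (1.0 + np.exp(-x / cfg.omega))


def asgd_minimize(
    cost_and_gradient,
    mu0: np.ndarray,
    config: ASGDConfig,
    scales: np.ndarray | float = 1.0,
):
    """Minimise a stochastic cost.

    ``cost_and_gradient(mu, iteration) -> (cost, grad)`` is expected to draw
    its own sample set from the iteration number, so the whole run is
    reproducible.  ``scales`` divides the gradient per parameter, equalising
    the effect of parameters with different natural units (e.g. affine matrix
    entries versus millimetre translations).

    Returns ``(mu_final, trace)`` where trace is a list of per-iteration dicts
    (iteration, cost, step, time, grad_norm).
    """
    mu = np.asarray(mu0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float) * np.ones_like(mu)

    a = config.a
    if a is None:
        gmax = 0.0
        g = np.zeros_like(mu)
        for k in range(config.n_probe):
            _, g = cost_and_gradient(mu, k)
            gmax += np.max(np.abs(g / scales))
        gmax /= max(config.n_probe, 1)
        # second probe one init_step away: at an already-converged start the
        # gradient is noise-level, but the cost may be steep nearby (e.g. a
        # strong penalty term); calibrate on the larger of the two magnitudes
        gn = np.max(np.abs(g / scales))
        if gn > 0:
            trial = mu - (config.init_step / gn) * (g / scales)
            _, gt_ = cost_and_gradient(trial, config.n_probe)
            gmax = max(gmax, np.max(np.abs(gt_ / scales)))
        a = config.init_step * (config.A + 1.0) ** config.alpha / max(gmax, 1e-12)
    # trust region: even a poorly scaled ``a`` (e.g. estimated from the tiny
    # gradients of an already-aligned pair) cannot launch the parameters away
    max_step = config.max_step if config.max_step is not None else 2.0 * config.init_step

    t = 0.0
    prev = None
    trace = []
    tail_start = int(np.ceil(config.max_iterations * (1.0 - config.average_tail)))
    tail_sum = np.zeros_like(mu)
    tail_n = 0
    for k in range(config.max_iterations):
        cost, grad = cost_and_gradient(mu, k)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {k}")
        g = grad / scales
        if prev is not None:
            denom = np.linalg.norm(g) * np.linalg.norm(prev)
            agreement = float(g @ prev) / denom if denom > 0 else 0.0
            t = max(0.0, t + _sigmoid_advance(-agreement, config))
        step = a / (t + config.A) ** config.alpha
        delta = step * g
        biggest = np.max(np.abs(delta))
        if biggest > max_step:
            # a capped update is evidence the step scale is overestimated
            delta *= max_step / biggest
            a *= 0.8
        mu = mu - delta
        if k >= tail_start:
            tail_sum += mu
            tail_n += 1
        trace.append(
            {
                "iteration": k,
                "cost": float(cost),
                "step": float(step),
                "time": float(t),
                "grad_norm": float(np.linalg.norm(g)),
            }
        )
        prev = g
    if tail_n > 0:
        # averaging the final iterates suppresses the stochastic noise floor
        # around the optimum (Polyak-style averaging)
        mu = tail_sum / tail_n
    return mu, trace


def gradient_descent(cost_and_gradient, mu0, step: float, iterations: int):
    """Fixed-step deterministic descent (dense sampling assumed upstream)."""
    mu = np.asarray(mu0, dtype=float).copy()
    trace = []
    for k in range(iterations):
        cost, grad = cost_and_gradient(mu, k)
        mu = mu - step * grad
        trace.append({"iteration": k, "cost": float(cost), "step": step,
                      "time": 0.0, "grad_norm": float(np.linalg.norm(grad))})
    return mu, trace
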