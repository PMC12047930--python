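"""Benchmark input/target series generators.

Four standard reservoir-computing benchmarks:

* memory capacity — i.i.d. uniform [0, 1] input; the readout reconstructs
  the input d steps in the past (open loop);
* NARMA-10 — a tenth-order nonlinear autoregressive moving-average
  recursion driven by uniform [0, 0.5] noise (open loop);
* Mackey-Glass — the chaotic delay differential equation
  dx/dt = xi*x(t-tau)/(1 + x(t-tau)^n) - gamma*x, integrated with RK4 at
  the sampling step 0.1 s (closed loop, one-step-ahead);
* partially observed Lorenz — the x coordinate of the chaotic Lorenz
  flow, RK4 at 0.01 s sampled every 0.02 s (closed loop).

The chaotic series are min-max normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateNormalizationError

logger = logging.getLogger(__name__)


@dataclass
class NarmaParams:
    """Coefficients of the NARMA-10 recursion."""

    p: float = 0.3
    q: float = 0.05
    g: float = 1.5
    D: float = 0.1


@dataclass
class MackeyGlassParams:
    """Mackey-Glass delay-differential parameters (chaotic at defaults)."""

    xi: float = 0.2
    gamma: float = 0.1
    tau: float = 17.0
    n: float = 10.0
    dt: float = 0.1


@dataclass
class LorenzParams:
    """Lorenz flow parameters (chaotic at defaults) and time steps."""

    a: float = 10.0
    b: float = 28.0
    c: float = 8.0 / 3.0
    integration_dt: float = 0.01
    sampling_dt: float = 0.02


def gen_uniform_input(
    T: int, low: float = 0.0, high: float = 1.0, rng_seed: int | None = None
) -> np.ndarray:
    """I.i.d. uniform input series on [low, high)."""
    if T <= 0:
        raise ValueError(f"series length must be positive, got {T}")
    if low >= high:
        raise ValueError(f"need low < high, got [{low}, {high})")
    rng = np.random.default_rng(rng_seed)
    return rng.uniform(low, high, T)


def gen_narma10(
    T: int,
    params: NarmaParams | None = None,
    rng_seed: int | None = None,
    max_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Input u (uniform [0, 0.5]) and NARMA-10 target y.

    y(t) = p*y(t-1) + q*y(t-1)*sum_{i=1..10} y(t-i) + g*u(t-10)*u(t-1) + D

    with zero initial history; the first 10 steps are burn-in. The
    recursion occasionally diverges for unlucky input draws; such series
    are discarded and regenerated from a fresh seed segment (logged).
    """
    if T <= 10:
        raise ValueError("NARMA-10 needs T > 10")
    params = params or NarmaParams()
    seeds = np.random.SeedSequence(rng_seed).spawn(max_restarts)
    for attempt, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        u = rng.uniform(0.0, 0.5, T)
        y = np.zeros(T)
        diverged = False
        for t in range(10, T):
            y[t] = (
                params.p * y[t - 1]
                + params.q * y[t - 1] * y[t - 10 : t].sum()
                + params.g * u[t - 10] * u[t - 1]
                + params.D
            )
            if abs(y[t]) > 1e6:
                diverged = True
                break
        if not diverged:
            return u, y
        logger.warning("NARMA-10 diverged (attempt %d); regenerating", attempt + 1)
    raise RuntimeError(f"NARMA-10 diverged in {max_restarts} consecutive attempts")


def integrate_mackey_glass(
    T_samples: int,
    params: MackeyGlassParams | None = None,
    history_value: float = 1.2,
    discard: int = 1000,
    normalize: bool = True,
    interpolate_delay: bool = True,
) -> np.ndarray:
    """RK4 integration of the Mackey-Glass equation with a delay ring buffer.

    The pre-history is constant at ``history_value``. The delayed term for
    the RK4 half-step stages is linearly interpolated between the buffer
    entries at t-tau and t-tau+dt (set ``interpolate_delay=False`` to hold
    it constant across the stages instead). The first ``discard`` samples
    are dropped and, by default, the emitted window is min-max normalized
    to [0, 1].
    """
    params = params or MackeyGlassParams()
    n_delay = params.tau / params.dt
    if abs(n_delay - round(n_delay)) > 1e-9:
        raise ValueError("tau must be an integer multiple of dt")
    n_delay = int(round(n_delay))
    total = T_samples + discard

    def f(x: float, x_del: float) -> float:
        return params.xi * x_del / (1.0 + x_del ** params.n) - params.gamma * x

    buf = np.empty(total + n_delay + 1)
    buf[: n_delay + 1] = history_value
    dt = params.dt
    for t in range(total):
        idx = t + n_delay  # buf[idx] = x(t)
        x = buf[idx]
        d0 = buf[t]           # x(t - tau)
        d1 = buf[t + 1]       # x(t - tau + dt)
        dh = 0.5 * (d0 + d1) if interpolate_delay else d0
        if not interpolate_delay:
            d1 = d0
        k1 = f(x, d0)
        k2 = f(x + 0.5 * dt * k1, dh)
        k3 = f(x + 0.5 * dt * k2, dh)
        k4 = f(x + dt * k3, d1)
        buf[idx + 1] = x + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if not np.isfinite(buf[idx + 1]):
            raise FloatingPointError(f"Mackey-Glass integration diverged at step {t}")
    series = buf[n_delay + 1 + discard :]
    if normalize:
        series, _ = normalize_series(series, series)
    return series


def integrate_lorenz(
    T_samples: int,
    params: LorenzParams | None = None,
    initial_xyz: tuple[float, float, float] = (1.0, 1.0, 1.0),
    discard: int = 500,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 integration of the Lorenz flow; returns (x_series, full_xyz).

    Integrates at ``integration_dt`` and keeps every
    ``sampling_dt/integration_dt``-th point. Only the x coordinate is
    exposed to the reservoir (partial observation); it is min-max
    normalized to [0, 1] after dropping ``discard`` samples. ``full_xyz``
    holds the raw (unnormalized) sampled state for reference.
    """
    params = params or LorenzParams()
    stride = params.sampling_dt / params.integration_dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("sampling_dt must be an integer multiple of integration_dt")
    stride = int(round(stride))
    n_steps = (T_samples + discard) * stride
    dt = params.integration_dt

    def f(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array(
            [params.a * (y - x), -x * z + params.b * x - y, x * y - params.c * z]
        )

    s = np.asarray(initial_xyz, dtype=float)
    sampled = np.empty(((n_steps // stride), 3))
    for t in range(n_steps):
        k1 = f(s)
        k2 = f(s + 0.5 * dt * k1)
        k3 = f(s + 0.5 * dt * k2)
        k4 = f(s + dt * k3)
        s = s + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if not np.isfinite(s).all():
            raise FloatingPointError(f"Lorenz integration diverged at step {t}")
        if (t + 1) % stride == 0:
            sampled[(t + 1) // stride - 1] = s
    sampled = sampled[discard:]
    x_series = sampled[:, 0].copy()
    if normalize:
        x_series, _ = normalize_series(x_series, x_series)
    return x_series, sampled


def normalize_series(
    series: np.ndarray, fit_segment: np.ndarray
) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine min-max map fitted on ``fit_segment``, applied to ``series``.

    Returns the normalized series and the (min, max) fit parameters; values
    outside the fit segment's range map outside [0, 1]. Fitting on the
    training segment only and reusing the parameters on test data avoids
    leakage.
    """
    fit_segment = np.asarray(fit_segment, dtype=float)
    lo, hi = float(fit_segment.min()), float(fit_segment.max())
    if hi - lo <= 0:
        raise DegenerateNormalizationError("fit segment is constant; cannot normalize")
    return (np.asarray(series, dtype=float) - lo) / (hi - lo), (lo, hi)


def denormalize_series(normalized: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`normalize_series` for stored (min, max) parameters."""
    lo, hi = params
    return np.asarray(normalized, dtype=float) * (hi - lo) + lo
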