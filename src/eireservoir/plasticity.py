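"""Homeostatic tuning of local excitatory-inhibitory balance.

Two routes drive each neuron toward a target firing rate rho_i:

* an online inhibitory plasticity rule — every inhibitory synapse into
  neuron i changes by delta*(r_i - rho_i) each step, so over-active neurons
  recruit more inhibition and under-active ones shed it; and
* a one-step "designed reservoir" rescaling — with full knowledge of the
  weights, each neuron's inhibitory inputs are multiplied by the factor
  Omega_i that places the mean-field fixed point exactly at the targets.

Targets are either homogeneous (all neurons share rho_T; 0.5 sits at the
sigmoid's linear midpoint and encodes exact local balance) or heterogeneous,
drawn from a symmetric Beta(a, a) on (0, 1) to mimic cortical firing-rate
diversity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

from .config import ReservoirConfig
from .connectivity import EIConnectivity, global_balance
from .dynamics import inverse_sigmoid
from .errors import AdaptationDivergedError

logger = logging.getLogger(__name__)

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"


@dataclass
class TargetRates:
    """Per-neuron target firing rates rho_i, all strictly inside (0, 1)."""

    rates: np.ndarray
    mode: str = HOMOGENEOUS
    homogeneous_value: float | None = None
    beta_shape: float | None = None


def sample_target_rates(
    mode: str,
    n_neurons: int,
    rho_T: float = 0.5,
    beta_shape: float = 5.0,
    rng_seed: int | None = None,
) -> TargetRates:
    """Build a target-rate vector.

    Homogeneous mode assigns ``rho_T`` to every neuron. Heterogeneous mode
    draws i.i.d. from Beta(a, a) with a = ``beta_shape`` (default 5, giving
    SD = 1/(2*sqrt(2a+1)) ~ 0.15 around the symmetric center 0.5).
    """
    if mode == HOMOGENEOUS:
        if not 0.0 < rho_T < 1.0:
            raise ValueError(f"rho_T must lie strictly in (0, 1), got {rho_T}")
        rates = np.full(n_neurons, float(rho_T))
        return TargetRates(rates, HOMOGENEOUS, homogeneous_value=rho_T)
    if mode == HETEROGENEOUS:
        if beta_shape <= 0:
            raise ValueError(f"beta_shape must be positive, got {beta_shape}")
        rng = np.random.default_rng(rng_seed)
        rates = rng.beta(beta_shape, beta_shape, size=n_neurons)
        # Beta(a,a) puts zero mass on the endpoints but floating point can
        # round there for tiny a; nudge inside the open interval.
        eps = np.finfo(float).tiny
        rates = np.clip(rates, eps, 1.0 - eps)
        return TargetRates(rates, HETEROGENEOUS, beta_shape=beta_shape)
    raise ValueError(f"unknown target mode {mode!r}")


def adapt_inhibitory(
    conn: EIConnectivity,
    rates: np.ndarray,
    targets: TargetRates,
    delta: float,
    clamp_at_zero: bool = False,
    inplace: bool = False,
) -> EIConnectivity:
    """One plasticity step: AI_ij += delta*(r_i - rho_i) on existing links.

    Only structurally present inhibitory links change; absent links and all
    excitatory weights are untouched. Without clamping, magnitudes may cross
    zero (the sign is folded into the effective matrix), which supports
    over-excited initial conditions.
    """
    if delta <= 0:
        raise ValueError("learning rate delta must be positive")
    out = conn if inplace else conn.copy()
    mask = out.inh_mask
    update = delta * (np.asarray(rates) - targets.rates)
    out.inh_weights[mask] += np.broadcast_to(update[:, None], out.inh_weights.shape)[mask]
    if clamp_at_zero:
        np.clip(out.inh_weights, 0.0, None, out=out.inh_weights)
    return out


@dataclass
class AdaptationTrace:
    """Record of one adaptation run."""

    beta: np.ndarray                       # global balance after each step
    eval_steps: np.ndarray                 # steps at which performance was scored
    eval_scores: np.ndarray                # scores (plasticity frozen during scoring)
    local_balance_initial: np.ndarray
    local_balance_final: np.ndarray


def run_adaptation(
    conn: EIConnectivity,
    config: ReservoirConfig,
    targets: TargetRates,
    n_steps: int,
    rng_seed: int | None = None,
    input_source: Callable[[int, np.random.Generator], np.ndarray] | None = None,
    eval_every: int | None = None,
    evaluator: Callable[[EIConnectivity], float] | None = None,
) -> tuple[EIConnectivity, AdaptationTrace]:
    """Drive the reservoir while the inhibitory plasticity rule runs.

    Each step draws one input sample (uniform on [0, 1] by default, matching
    the memory benchmark's input distribution), advances the rate dynamics,
    then applies :func:`adapt_inhibitory`. The global balance is recorded
    every step; if ``eval_every`` and ``evaluator`` are given, plasticity is
    frozen every ``eval_every`` steps, the evaluator scores the current
    connectivity (training its own readout on fresh input), and adaptation
    resumes.

    Because the rule adds the same scalar delta*(r_i - rho_i) to every
    inhibitory link into neuron i, the inhibitory matrix stays within
    AI(t) = AI(0) + C_i(t) on the structural mask, with C the per-neuron
    cumulative correction. The unclamped loop tracks C instead of rewriting
    the N x N matrix each step; clamped runs fall back to dense updates.
    """
    rng = np.random.default_rng(config.seed + 1 if rng_seed is None else rng_seed)
    if input_source is None:
        input_source = lambda n, g: g.uniform(0.0, 1.0, n)
    u = np.asarray(input_source(n_steps, rng), dtype=float)

    delta = config.learning_rate
    theta, c, lam = config.threshold, config.sigmoid_steepness, config.leakage
    clamp = config.clamp_inhibitory_at_zero

    work = conn.copy()
    _, local0 = global_balance(work)
    mask = work.inh_mask
    m_counts = mask.sum(axis=1)
    alpha = work.scaling

    beta_trace = np.empty(n_steps)
    eval_steps: list[int] = []
    eval_scores: list[float] = []

    n = work.n_neurons
    v = np.zeros(n)
    r = expit(c * (v - theta))
    rho = targets.rates

    if not clamp:
        W0 = work.effective_matrix
        win = work.input_weights
        C = np.zeros(n)
        exc_row = alpha * work.exc_weights.sum(axis=1)
        inh_row0 = alpha * work.inh_weights.sum(axis=1)

        def materialize() -> EIConnectivity:
            snap = work.copy()
            snap.inh_weights[mask] += np.broadcast_to(C[:, None], mask.shape)[mask]
            return snap

        for t in range(n_steps):
            drive = W0 @ r - alpha * (C * (mask @ r)) + win * u[t]
            v = lam * v + drive if lam != 0.0 else drive
            r = expit(c * (v - theta))
            if not np.isfinite(v).all():
                raise AdaptationDivergedError(
                    f"non-finite state during adaptation at step {t}", step=t
                )
            C += delta * (r - rho)
            beta_trace[t] = (exc_row - inh_row0 - alpha * C * m_counts).mean()
            if eval_every and evaluator and (t + 1) % eval_every == 0:
                eval_steps.append(t + 1)
                eval_scores.append(float(evaluator(materialize())))
        final = materialize()
    else:
        win = work.input_weights
        # keep the structural mask fixed: a link clamped at zero may recover
        update = np.zeros_like(work.inh_weights)
        for t in range(n_steps):
            W = work.effective_matrix
            drive = W @ r + win * u[t]
            v = lam * v + drive if lam != 0.0 else drive
            r = expit(c * (v - theta))
            if not np.isfinite(v).all():
                raise AdaptationDivergedError(
                    f"non-finite state during adaptation at step {t}", step=t
                )
            update[mask] = np.broadcast_to(
                (delta * (r - rho))[:, None], mask.shape
            )[mask]
            np.clip(work.inh_weights + update, 0.0, None, out=work.inh_weights)
            beta_trace[t] = global_balance(work)[0]
            if eval_every and evaluator and (t + 1) % eval_every == 0:
                eval_steps.append(t + 1)
                eval_scores.append(float(evaluator(work.copy())))
        final = work

    _, local1 = global_balance(final)
    trace = AdaptationTrace(
        beta=beta_trace,
        eval_steps=np.asarray(eval_steps, dtype=int),
        eval_scores=np.asarray(eval_scores, dtype=float),
        local_balance_initial=local0,
        local_balance_final=local1,
    )
    return final, trace


def design_rescale(
    conn: EIConnectivity,
    targets: TargetRates,
    mean_input: float,
    theta: float,
    c: float,
) -> EIConnectivity:
    """One-step designed reservoir: rescale inhibition to hit target rates.

    Each neuron's inhibitory inputs are multiplied by the factor Omega_i
    solving the mean-field fixed-point condition — with every presynaptic
    rate at its target and the input at its mean, the post-activation rate
    equals rho_i:

        alpha * (sum_j AE_ij rho_j - Omega_i sum_j AI_ij rho_j)
            + Win_i <u>  =  theta + Sig^{-1}(rho_i)

    Neurons whose target-weighted inhibitory sum is zero are left unscaled
    (warning); a negative Omega_i flips the sign of that neuron's
    inhibition and is allowed but warned about.
    """
    rho = targets.rates
    alpha = conn.scaling
    exc_drive = alpha * (conn.exc_weights @ rho)
    inh_drive = alpha * (conn.inh_weights @ rho)
    required = exc_drive + conn.input_weights * mean_input - theta - inverse_sigmoid(rho, c)

    out = conn.copy()
    zero_den = np.isclose(inh_drive, 0.0)
    if zero_den.any():
        warnings.warn(
            f"{int(zero_den.sum())} neuron(s) have zero target-weighted inhibitory "
            "input and were left unscaled",
            stacklevel=2,
        )
    omega = np.ones(conn.n_neurons)
    np.divide(required, inh_drive, out=omega, where=~zero_den)
    if np.any(omega[~zero_den] < 0):
        warnings.warn(
            f"{int((omega[~zero_den] < 0).sum())} neuron(s) need negative Omega: "
            "their inhibitory inputs flip sign",
            stacklevel=2,
        )
    out.inh_weights *= omega[:, None]
    return out
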