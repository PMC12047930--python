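"""Discrete-time rate dynamics of the sigmoid reservoir.

One reservoir step equals one input sample. Membrane potentials integrate
recurrent and external drive,

    V(t+dt) = lambda*V(t) + alpha*(AE - AI) r(t) + Win u(t),

and firing rates are read through a logistic activation with steepness c
and threshold theta,

    r(t+dt) = 1 / (1 + exp(-c * (V(t+dt) - theta))).

With leakage lambda = 0 (the default) individual neurons carry no memory;
all memory lives in the recurrent network state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .connectivity import EIConnectivity
from .errors import SimulationDivergedError


def sigmoid(x, c: float):
    """Logistic activation Sig(x) = 1/(1+exp(-c x)), monotone with range (0, 1)."""
    return expit(c * np.asarray(x, dtype=float))


def inverse_sigmoid(rho, c: float):
    """Inverse of :func:`sigmoid`: (1/c) * ln(rho / (1-rho)) for rho in (0, 1)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0.0) or np.any(rho >= 1.0):
        raise ValueError("inverse_sigmoid requires rates strictly inside (0, 1)")
    return logit(rho) / c


@dataclass
class ReservoirState:
    """Instantaneous state: potentials V, rates r, and the step counter."""

    potentials: np.ndarray
    rates: np.ndarray
    time_index: int = 0

    @classmethod
    def initial(cls, n_neurons: int, theta: float, c: float) -> "ReservoirState":
        """Resting state V=0, r=Sig(-theta); the washout discards the transient."""
        v = np.zeros(n_neurons)
        return cls(potentials=v, rates=sigmoid(v - theta, c), time_index=0)


@dataclass
class ReservoirTrajectory:
    """Time-indexed rate (and optionally potential) matrices, shape (T, N)."""

    rates: np.ndarray
    potentials: np.ndarray | None = None

    def __len__(self) -> int:
        return self.rates.shape[0]


def step(
    state: ReservoirState,
    conn: EIConnectivity,
    u: float,
    theta: float,
    c: float,
    lam: float = 0.0,
) -> ReservoirState:
    """Advance the reservoir by one input sample."""
    v = lam * state.potentials + conn.effective_matrix @ state.rates + conn.input_weights * u
    if not np.all(np.isfinite(v)):
        raise SimulationDivergedError(
            f"non-finite membrane potential at step {state.time_index + 1}",
            step=state.time_index + 1,
        )
    return ReservoirState(
        potentials=v, rates=sigmoid(v - theta, c), time_index=state.time_index + 1
    )


def run(
    conn: EIConnectivity,
    input_series: np.ndarray,
    theta: float,
    c: float,
    lam: float = 0.0,
    initial_state: ReservoirState | None = None,
    record_potentials: bool = False,
) -> ReservoirTrajectory:
    """Iterate :func:`step` over a finite input series.

    Deterministic given the connectivity, inputs and initial state. The
    inner loop precomputes the effective matrix once and checks for
    numerical blow-up every step.
    """
    u = np.asarray(input_series, dtype=float)
    n = conn.n_neurons
    T = u.shape[0]
    if initial_state is None:
        initial_state = ReservoirState.initial(n, theta, c)
    rates = np.empty((T, n))
    pots = np.empty((T, n)) if record_potentials else None

    W = conn.effective_matrix
    win = conn.input_weights
    v = initial_state.potentials
    r = initial_state.rates
    for t in range(T):
        v = lam * v + W @ r + win * u[t] if lam != 0.0 else W @ r + win * u[t]
        r = expit(c * (v - theta))
        if not np.isfinite(v).all():
            raise SimulationDivergedError(
                f"non-finite membrane potential at step {t}", step=t
            )
        rates[t] = r
        if pots is not None:
            pots[t] = v
    return ReservoirTrajectory(rates=rates, potentials=pots)
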