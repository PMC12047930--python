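"""Readout training and open/closed-loop evaluation.

Only the output layer of a reservoir computer is trained: reservoir states
are harvested while the network is driven by the input, a washout
transient is discarded, and a linear readout is fitted by ridge regression
(regularization eta, unpenalized intercept). Evaluation runs either

* open loop — the reservoir keeps receiving the true input and the
  readout predicts the target at each step; or
* closed loop — the readout is trained for one-step-ahead prediction
  (teacher forcing), then after a priming segment its own prediction is
  fed back as the next input, producing an autonomous forecast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import Ridge

from .connectivity import EIConnectivity
from .dynamics import ReservoirState, run

FEEDBACK_DIVERGENCE_LIMIT = 1e6


@dataclass
class SplitSpec:
    """Washout / train / test lengths in reservoir steps."""

    washout: int = 500
    train: int = 20_000
    test: int = 5_000

    @property
    def total(self) -> int:
        return self.washout + self.train + self.test


@dataclass
class ReadoutModel:
    """Trained linear readout: y = states @ weights + intercept."""

    weights: np.ndarray          # (N, M)
    intercept: np.ndarray        # (M,)
    ridge_penalty: float

    def predict(self, states: np.ndarray) -> np.ndarray:
        return states @ self.weights + self.intercept


def harvest_states(
    conn: EIConnectivity,
    input_series: np.ndarray,
    theta: float,
    c: float,
    lam: float = 0.0,
    split: SplitSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the reservoir and return (train_states, test_states).

    The readout sees the firing rates of all N neurons; the first
    ``split.washout`` states are discarded as transient.
    """
    split = split or SplitSpec()
    if len(input_series) < split.total:
        raise ValueError(
            f"input series has {len(input_series)} samples; "
            f"split needs {split.total}"
        )
    traj = run(conn, input_series[: split.total], theta, c, lam)
    states = traj.rates
    train = states[split.washout : split.washout + split.train]
    test = states[split.washout + split.train : split.total]
    return train, test


def fit_ridge_readout(
    states: np.ndarray,
    targets: np.ndarray,
    eta: float,
    fit_intercept: bool = True,
) -> ReadoutModel:
    """Ridge regression of targets on states: min ||S W - Y||^2 + eta ||W||^2.

    The intercept is obtained by mean-centering and is not penalized.
    """
    if eta < 0:
        raise ValueError("ridge penalty must be non-negative")
    targets = np.asarray(targets, dtype=float)
    squeeze = targets.ndim == 1
    Y = targets[:, None] if squeeze else targets
    model = Ridge(alpha=eta, fit_intercept=fit_intercept, solver="cholesky")
    model.fit(states, Y)
    weights = model.coef_.reshape(Y.shape[1], -1).T  # sklearn squeezes M=1
    return ReadoutModel(
        weights=np.ascontiguousarray(weights),
        intercept=np.atleast_1d(model.intercept_).astype(float),
        ridge_penalty=eta,
    )


def predict_open_loop(
    conn: EIConnectivity,
    model: ReadoutModel,
    input_series: np.ndarray,
    theta: float,
    c: float,
    lam: float = 0.0,
    washout: int = 0,
) -> np.ndarray:
    """Drive the reservoir with the true inputs and read out predictions.

    Returns one prediction row per post-washout input sample.
    """
    traj = run(conn, input_series, theta, c, lam)
    return model.predict(traj.rates[washout:])


def predict_closed_loop(
    conn: EIConnectivity,
    model: ReadoutModel,
    primer_series: np.ndarray,
    horizon: int,
    theta: float,
    c: float,
    lam: float = 0.0,
    feedback_override: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Autonomous forecast: prime with true data, then feed back predictions.

    The feedback enters through the same input weights the primer used.
    Returns (predictions of length <= horizon, diverged flag); the forecast
    stops early if the fed-back value blows up. Passing the true
    continuation as ``feedback_override`` replaces the fed-back predictions
    with it (teacher forcing), which must reproduce the open-loop output.
    """
    W = conn.effective_matrix
    win = conn.input_weights
    state = ReservoirState.initial(conn.n_neurons, theta, c)
    v, r = state.potentials, state.rates
    for u_t in np.asarray(primer_series, dtype=float):
        v = (lam * v if lam != 0.0 else 0.0) + W @ r + win * u_t
        r = expit(c * (v - theta))
    preds = np.empty(horizon)
    u_t = float(model.predict(r[None, :])[0, 0])
    for t in range(horizon):
        preds[t] = u_t
        if not np.isfinite(u_t) or abs(u_t) > FEEDBACK_DIVERGENCE_LIMIT:
            return preds[: t + 1], True
        fed = u_t if feedback_override is None else float(feedback_override[t])
        v = (lam * v if lam != 0.0 else 0.0) + W @ r + win * fed
        r = expit(c * (v - theta))
        u_t = float(model.predict(r[None, :])[0, 0])
    return preds, False
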