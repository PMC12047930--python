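"""Construction of Dale's-law excitatory-inhibitory connectivity.

A reservoir of N sigmoid neurons is split into excitatory and inhibitory
populations. Each neuron's outgoing synapses are all of its own sign
(Dale's law), so the recurrent matrix decomposes as W = alpha*(AE - AI)
with AE holding excitatory link strengths and AI inhibitory ones. The
global balance parameter beta — the population mean of the signed row sums
of W — is controlled by setting the mean inhibitory strength while leaving
excitation fixed.

Sign convention: AI stores the subtracted matrix directly. In the normal
regime the signed mean inhibitory strength w_I is negative and AI entries
are positive magnitudes; when beta is pushed past the total excitation
(w_I > 0) the labeled-inhibitory links act excitatory, which is represented
by negative AI entries. A single linear formula covers both regimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ReservoirConfig
from .errors import InfeasibleBalanceError, InvalidConfigError

logger = logging.getLogger(__name__)

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass
class EIConnectivity:
    """Weights of one reservoir realization.

    ``exc_weights`` (AE) is non-negative always; ``inh_weights`` (AI) is
    non-negative by convention but entries may pass through zero or start
    negative when representing over-excited (beta > total excitation)
    regimes. Rows index the postsynaptic neuron. The effective recurrent
    matrix is ``scaling * (exc_weights - inh_weights)``.
    """

    exc_weights: np.ndarray
    inh_weights: np.ndarray
    input_weights: np.ndarray
    neuron_type: np.ndarray
    scaling: float = 1.0

    @property
    def n_neurons(self) -> int:
        return self.exc_weights.shape[0]

    @property
    def effective_matrix(self) -> np.ndarray:
        """W = alpha * (AE - AI)."""
        return self.scaling * (self.exc_weights - self.inh_weights)

    @property
    def inh_mask(self) -> np.ndarray:
        """Boolean mask of structurally present inhibitory links."""
        return self.inh_weights != 0.0

    def copy(self) -> "EIConnectivity":
        return EIConnectivity(
            exc_weights=self.exc_weights.copy(),
            inh_weights=self.inh_weights.copy(),
            input_weights=self.input_weights.copy(),
            neuron_type=self.neuron_type.copy(),
            scaling=self.scaling,
        )

    def save(self, path: str | Path) -> None:
        """Snapshot to a compressed array archive for reproducibility."""
        np.savez_compressed(
            path,
            exc_weights=self.exc_weights,
            inh_weights=self.inh_weights,
            input_weights=self.input_weights,
            neuron_type=self.neuron_type,
            scaling=np.asarray(self.scaling),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EIConnectivity":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                exc_weights=data["exc_weights"],
                inh_weights=data["inh_weights"],
                input_weights=data["input_weights"],
                neuron_type=data["neuron_type"],
                scaling=float(data["scaling"]),
            )


def signed_mean_inh_for_beta(beta: float, config: ReservoirConfig) -> float:
    """Signed mean inhibitory strength w_I realizing global balance ``beta``.

    The expected local balance of a neuron with k*fE excitatory in-links of
    mean strength muE and k*fI inhibitory in-links of signed mean w_I is
    alpha*(k*fE*muE + k*fI*w_I); solving for w_I gives

        w_I = (beta/alpha - k*fE*muE) / (k*fI).

    Negative w_I is net inhibitory (the normal regime); w_I >= 0 means the
    labeled-inhibitory population has lost its inhibitory effect.
    """
    k = config.mean_in_degree
    k_inh = k * config.inh_fraction
    total_exc = k * config.exc_fraction * config.mean_exc_strength
    if k_inh <= 0:
        if np.isclose(beta, config.scaling_factor * total_exc):
            return 0.0
        raise InfeasibleBalanceError(
            f"no inhibitory in-links (k*fI={k_inh}); cannot realize beta={beta}"
        )
    w_inh = (beta / config.scaling_factor - total_exc) / k_inh
    if w_inh > 0:
        logger.info(
            "requested balance beta=%.3g exceeds total excitation: labeled-"
            "inhibitory links act excitatory (w_I=%.3g > 0)", beta, w_inh,
        )
    return w_inh


def _split_in_degrees(k: float, frac: float, n: int, rng: np.random.Generator):
    """Per-neuron excitatory in-degree: k*frac, stochastically rounded."""
    target = k * frac
    base = int(np.floor(target))
    extra = rng.random(n) < (target - base)
    return base + extra.astype(int)


def build_connectivity(config: ReservoirConfig, rng_seed: int | None = None) -> EIConnectivity:
    """Draw one reservoir realization at the configured global balance.

    Each neuron receives on average ``k`` incoming links: k*fE drawn without
    replacement from the excitatory population and k*fI from the inhibitory
    one (self-loops permitted), giving 10% connectivity at defaults.
    Excitatory strengths are Gaussian(muE, sigmaE) truncated at 0; the
    inhibitory draws are Gaussian(|w_I|, sigmaI) truncated at 0, entered
    into AI with the sign dictated by w_I (see module docstring). Input
    weights: a random fraction fin of neurons (both types eligible) get
    weights uniform on [-sigma_in/2, sigma_in/2]; the rest are zero.
    """
    if config.n_neurons <= 0 or config.mean_in_degree <= 0:
        raise InvalidConfigError("n_neurons and mean_in_degree must be positive")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    n = config.n_neurons
    n_exc = int(round(n * config.exc_fraction))
    if n_exc in (0, n):
        raise InvalidConfigError("both populations must be non-empty at this n_neurons")

    is_exc = np.arange(n) < n_exc
    neuron_type = np.where(is_exc, EXCITATORY, INHIBITORY)

    w_inh = signed_mean_inh_for_beta(config.balance, config)
    inh_sign = 1.0 if w_inh < 0 else (-1.0 if w_inh > 0 else 0.0)

    exc_pool = np.flatnonzero(is_exc)
    inh_pool = np.flatnonzero(~is_exc)
    k_exc_per = _split_in_degrees(config.mean_in_degree, config.exc_fraction, n, rng)
    k_inh_per = _split_in_degrees(config.mean_in_degree, config.inh_fraction, n, rng)

    exc_weights = np.zeros((n, n))
    inh_weights = np.zeros((n, n))
    for i in range(n):
        pre_e = rng.choice(exc_pool, size=min(k_exc_per[i], exc_pool.size), replace=False)
        w_e = rng.normal(config.mean_exc_strength, config.exc_strength_spread, pre_e.size)
        exc_weights[i, pre_e] = np.clip(w_e, 0.0, None)

        pre_i = rng.choice(inh_pool, size=min(k_inh_per[i], inh_pool.size), replace=False)
        if inh_sign == 0.0:
            # w_I exactly 0: symmetric draws, no truncation (truncating a
            # zero-mean Gaussian would bias the balance)
            inh_weights[i, pre_i] = rng.normal(0.0, config.inh_strength_spread, pre_i.size)
        else:
            mags = rng.normal(abs(w_inh), config.inh_strength_spread, pre_i.size)
            inh_weights[i, pre_i] = inh_sign * np.clip(mags, 0.0, None)

    n_in = int(round(n * config.input_fraction))
    input_weights = np.zeros(n)
    fed = rng.choice(n, size=n_in, replace=False)
    input_weights[fed] = rng.uniform(-config.input_spread / 2, config.input_spread / 2, n_in)

    return EIConnectivity(
        exc_weights=exc_weights,
        inh_weights=inh_weights,
        input_weights=input_weights,
        neuron_type=neuron_type,
        scaling=config.scaling_factor,
    )


def global_balance(conn: EIConnectivity) -> tuple[float, np.ndarray]:
    """Measured global balance and per-neuron local balances.

    The local balance of neuron i is the signed sum of its incoming
    recurrent weights, beta_i = sum_j alpha*(AE_ij - AI_ij); the global
    balance is the population mean of the beta_i.
    """
    local = conn.effective_matrix.sum(axis=1)
    return float(local.mean()), local
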