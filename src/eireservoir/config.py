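"""Reservoir hyperparameter container.

All scalar knobs of the excitatory-inhibitory reservoir live here: network
size and composition, synaptic strength statistics, the global balance
parameter beta, activation parameters, input layer statistics, and the
learning-rule constants. Defaults correspond to the standard study
configuration: a 500-neuron network with a 4:1 excitatory:inhibitory split,
average in-degree 50 (10% connectivity), mean excitatory strength
1/(k*fE) = 0.025, and a balanced network (beta = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .errors import InvalidConfigError


@dataclass
class ReservoirConfig:
    """Hyperparameters of an excitatory-inhibitory reservoir.

    Parameters
    ----------
    n_neurons:
        Total neuron count N.
    exc_fraction:
        Fraction fE of neurons labeled excitatory; the inhibitory fraction
        is fI = 1 - fE exactly.
    mean_in_degree:
        Average number k of incoming recurrent links per neuron.
    mean_exc_strength:
        Mean excitatory synaptic strength muE. ``None`` (default) resolves
        to 1/(k*fE) so a balanced network has unit total excitation.
    exc_strength_spread, inh_strength_spread:
        Gaussian standard deviations of the synaptic strength draws;
        ``None`` resolves to 0.2*muE for both.
    balance:
        Target global balance beta: mean signed sum of incoming recurrent
        weights. 0 is balanced, negative inhibition-dominated, positive
        excitation-dominated.
    scaling_factor:
        Overall multiplier alpha applied to the recurrent matrix.
    threshold:
        Activation threshold theta, shared by all neurons.
    sigmoid_steepness:
        Steepness c of the logistic activation 1/(1+exp(-c*x)).
    input_fraction:
        Fraction fin of neurons (either type) receiving external input.
    input_spread:
        Input link scaling sigma_in: nonzero input weights are uniform on
        [-sigma_in/2, sigma_in/2].
    leakage:
        Leakage constant lambda; 0 means neurons keep no memory of their
        previous potential.
    ridge_penalty:
        Ridge regularization eta used when training the readout.
    learning_rate:
        Inhibitory plasticity learning rate delta.
    seed:
        Base seed for connectivity construction.
    clamp_inhibitory_at_zero:
        If True, plasticity never drives an inhibitory magnitude below 0.
    """

    n_neurons: int = 500
    exc_fraction: float = 0.8
    mean_in_degree: float = 50.0
    mean_exc_strength: float | None = None
    exc_strength_spread: float | None = None
    inh_strength_spread: float | None = None
    balance: float = 0.0
    scaling_factor: float = 1.0
    threshold: float = 0.0
    sigmoid_steepness: float = 10.0
    input_fraction: float = 0.3
    input_spread: float = 0.1
    leakage: float = 0.0
    ridge_penalty: float = 1e-7
    learning_rate: float = 1e-3
    seed: int = 0
    clamp_inhibitory_at_zero: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise InvalidConfigError(f"n_neurons must be positive, got {self.n_neurons}")
        if not 0.0 < self.exc_fraction < 1.0:
            raise InvalidConfigError(
                f"exc_fraction must lie strictly in (0, 1), got {self.exc_fraction}"
            )
        if self.mean_in_degree <= 0:
            raise InvalidConfigError(
                f"mean_in_degree must be positive, got {self.mean_in_degree}"
            )
        if self.mean_in_degree > self.n_neurons:
            raise InvalidConfigError("mean_in_degree cannot exceed n_neurons")
        if self.mean_exc_strength is None:
            self.mean_exc_strength = 1.0 / (self.mean_in_degree * self.exc_fraction)
        if self.exc_strength_spread is None:
            self.exc_strength_spread = 0.2 * self.mean_exc_strength
        if self.inh_strength_spread is None:
            self.inh_strength_spread = self.exc_strength_spread

    @property
    def inh_fraction(self) -> float:
        """Inhibitory fraction fI = 1 - fE."""
        return 1.0 - self.exc_fraction

    def with_updates(self, **kwargs) -> "ReservoirConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReservoirConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
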