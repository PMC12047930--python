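"""Exception hierarchy for the package."""


class EIReservoirError(Exception):
    """Base class for package-specific errors."""


class InvalidConfigError(EIReservoirError, ValueError):
    """A reservoir configuration violates its invariants."""


class InfeasibleBalanceError(EIReservoirError, ValueError):
    """The requested global balance cannot be realized (e.g. no inhibitory links)."""


class SimulationDivergedError(EIReservoirError, FloatingPointError):
    """Membrane potentials became non-finite during simulation."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class AdaptationDivergedError(SimulationDivergedError):
    """Firing rates became non-finite during inhibitory adaptation."""


class DegenerateNormalizationError(EIReservoirError, ValueError):
    """Min-max normalization was asked to fit a constant segment."""
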