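"""Performance scores and dynamical characterization.

Task scores: delay reconstruction R^2 and memory capacity (their sum over
delays 1..70), RMSE / NRMSE for one-step prediction, and valid prediction
time (VPT) for closed-loop forecasts. Dynamics: per-neuron differential
entropy (Kozachenko-Leonenko first-nearest-neighbor estimator), mean
pairwise correlation, mean firing rate, and a coarse regime label
(silent / saturated / synchronized / active).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

D_MAX_DEFAULT = 70
VPT_THRESHOLD_DEFAULT = 0.4

SILENT = "silent"
SATURATED = "saturated"
SYNCHRONIZED = "synchronized"
ACTIVE = "active"

# regime thresholds: mean rate < 0.05 silent, > 0.95 saturated,
# mean pairwise correlation > 0.9 synchronized
RATE_SILENT = 0.05
RATE_SATURATED = 0.95
CORR_SYNCHRONIZED = 0.9


@dataclass
class MetricsReport:
    """Flat summary of one reservoir evaluation."""

    memory_capacity: float | None = None
    r2_curve: np.ndarray | None = None
    rmse: float | None = None
    nrmse: float | None = None
    vpt: float | None = None
    neuron_entropies: np.ndarray | None = None
    mean_rate: float | None = None
    mean_pairwise_correlation: float | None = None
    regime: str | None = None
    beta: float | None = None

    def to_dict(self) -> dict:
        out = {}
        for key, value in self.__dict__.items():
            if value is None:
                continue
            if isinstance(value, np.ndarray):
                out[key] = value.tolist()
            else:
                out[key] = value
        return out


def delay_r2(u: np.ndarray, y: np.ndarray, d: int) -> float:
    """Squared Pearson correlation between u(t-d) and the delay-d readout.

    ``u`` is the input series and ``y`` the readout's output aligned with
    the last ``len(y)`` samples of ``u``; the correlation is computed on
    the overlap where u(t-d) exists. Zero variance on either side yields 0
    (a silent reservoir has no recall) with a warning.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = len(u) - len(y)
    if offset < 0:
        raise ValueError("prediction series longer than input series")
    start = max(0, d - offset)
    target = u[offset - d + start : len(u) - d]
    pred = y[start:]
    if len(pred) < 2:
        raise ValueError("overlapping window too short for a correlation")
    vu, vy = target.var(), pred.var()
    if vu == 0.0 or vy == 0.0:
        warnings.warn("zero variance in delay_r2; returning 0", stacklevel=2)
        return 0.0
    cov = np.cov(target, pred, ddof=0)[0, 1]
    return float(cov * cov / (vu * vy))


def memory_capacity(
    u: np.ndarray, predictions_per_delay: np.ndarray, d_max: int = D_MAX_DEFAULT
) -> tuple[float, np.ndarray]:
    """Memory capacity MC = sum of R^2 over delays 1..d_max.

    ``predictions_per_delay`` has one column per delay d = 1..d_max, each
    aligned with the last ``len(predictions)`` samples of ``u``. MC is the
    area under the R^2-versus-delay step curve. Returns (MC, r2_curve).
    """
    predictions_per_delay = np.asarray(predictions_per_delay, dtype=float)
    if predictions_per_delay.ndim != 2 or predictions_per_delay.shape[1] != d_max:
        raise ValueError(
            f"need one prediction column per delay 1..{d_max}, "
            f"got shape {predictions_per_delay.shape}"
        )
    r2 = np.array(
        [delay_r2(u, predictions_per_delay[:, d - 1], d) for d in range(1, d_max + 1)]
    )
    return float(r2.sum()), r2


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def nrmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """RMSE normalized by the standard deviation of the true series."""
    sd = float(np.std(np.asarray(y_true, dtype=float)))
    if sd == 0.0:
        raise ValueError("true series is constant; NRMSE undefined")
    return rmse(y_true, y_pred) / sd


@dataclass
class VPTResult:
    """Valid prediction time with a censoring flag (never exceeded)."""

    seconds: float
    censored: bool

    def __float__(self) -> float:
        return self.seconds


def valid_prediction_time(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    dt: float = 1.0,
    threshold: float = VPT_THRESHOLD_DEFAULT,
    pointwise: bool = False,
) -> VPTResult:
    """First time the forecast's normalized error exceeds ``threshold``.

    By default the error at step t is the running NRMSE — the RMSE over
    steps 0..t divided by the true series' standard deviation over the
    whole evaluation window. ``pointwise=True`` uses the instantaneous
    normalized absolute error instead. If the threshold is never exceeded
    the result is censored at the full horizon.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0 or len(y_pred) == 0:
        raise ValueError("empty series")
    L = min(len(y_true), len(y_pred))
    y_true, y_pred = y_true[:L], y_pred[:L]
    sd = float(np.std(y_true))
    if sd == 0.0:
        raise ValueError("true series is constant; normalized error undefined")
    sq = (y_true - y_pred) ** 2
    if pointwise:
        err = np.sqrt(sq) / sd
    else:
        err = np.sqrt(np.cumsum(sq) / np.arange(1, L + 1)) / sd
    exceeded = np.flatnonzero(err > threshold)
    if exceeded.size == 0:
        return VPTResult(seconds=dt * L, censored=True)
    return VPTResult(seconds=dt * float(exceeded[0]), censored=False)


def neuron_differential_entropy(
    rate_series: np.ndarray,
    max_samples: int = 5000,
    jitter: float = 1e-12,
    rng_seed: int = 0,
) -> float:
    """Nonparametric differential entropy of one neuron's rate series (nats).

    Kozachenko-Leonenko first-nearest-neighbor estimator for scalar
    samples:

        H ~ psi(T) - psi(1) + (1/T) * sum_i ln(2 * nn_dist_i)

    Ties are broken by a tiny uniform jitter; series longer than
    ``max_samples`` are subsampled (deterministically, via ``rng_seed``)
    for speed. A constant series has no continuous spread and returns
    -inf (silent/saturated neurons).
    """
    x = np.asarray(rate_series, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples for the entropy estimate")
    if np.ptp(x) == 0.0:
        return float("-inf")
    rng = np.random.default_rng(rng_seed)
    if x.size > max_samples:
        x = rng.choice(x, size=max_samples, replace=False)
    x = np.sort(x + rng.uniform(-jitter, jitter, x.size))
    gaps = np.diff(x)
    nn = np.empty(x.size)
    nn[0] = gaps[0]
    nn[-1] = gaps[-1]
    if x.size > 2:
        nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    nn = np.maximum(nn, np.finfo(float).tiny)
    T = x.size
    return float(digamma(T) - digamma(1) + np.mean(np.log(2.0 * nn)))


def mean_pairwise_correlation(rates: np.ndarray) -> tuple[float, int]:
    """Mean Pearson correlation over all unordered neuron pairs.

    Neurons with zero variance are excluded from the average; the second
    return value counts them. Shape of ``rates`` is (T, N).
    """
    rates = np.asarray(rates, dtype=float)
    variances = rates.var(axis=0)
    keep = variances > 0.0
    n_excluded = int((~keep).sum())
    kept = rates[:, keep]
    if kept.shape[1] < 2:
        return float("nan"), n_excluded
    corr = np.corrcoef(kept, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean()), n_excluded


def mean_rate(rates: np.ndarray) -> float:
    """Time-and-population mean firing rate."""
    return float(np.asarray(rates).mean())


def classify_regime(rates: np.ndarray) -> str:
    """Coarse dynamical regime of a rate trajectory (T, N).

    silent: mean rate < 0.05; saturated: > 0.95; synchronized: mean
    pairwise correlation > 0.9 at intermediate rates; otherwise active.
    The classes are mutually exclusive and exhaustive.
    """
    r_bar = mean_rate(rates)
    if r_bar < RATE_SILENT:
        return SILENT
    if r_bar > RATE_SATURATED:
        return SATURATED
    corr, _ = mean_pairwise_correlation(rates)
    if np.isfinite(corr) and corr > CORR_SYNCHRONIZED:
        return SYNCHRONIZED
    return ACTIVE
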