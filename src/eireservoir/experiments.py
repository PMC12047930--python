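"""Scripted, seeded experiment designs.

Reproducible sweeps and comparisons over the reservoir's two global knobs
(balance beta, threshold theta) and the input link scaling sigma_in, and
head-to-head comparisons of tuning strategies:

* non-adaptive, globally tuned — exhaustive (beta, theta) grid search;
* adaptive — homeostatic inhibitory plasticity toward homogeneous
  (tuned rho_T) or heterogeneous (Beta-distributed) target rates;
* designed — the one-step inhibitory rescaling toward the same targets.

Every cell of every sweep carries the integer seeds used, so any cell can
be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ReservoirConfig
from .connectivity import EIConnectivity, build_connectivity, global_balance
from .learning import SplitSpec, fit_ridge_readout, harvest_states, predict_closed_loop
from .metrics import (
    classify_regime,
    memory_capacity,
    mean_pairwise_correlation,
    mean_rate,
    neuron_differential_entropy,
    rmse,
    valid_prediction_time,
)
from .plasticity import (
    HETEROGENEOUS,
    HOMOGENEOUS,
    design_rescale,
    run_adaptation,
    sample_target_rates,
)
from .tasks import (
    LorenzParams,
    MackeyGlassParams,
    gen_narma10,
    gen_uniform_input,
    integrate_lorenz,
    integrate_mackey_glass,
)

logger = logging.getLogger(__name__)

MEMORY = "memory"
NARMA10 = "narma10"
MACKEY_GLASS = "mackey_glass"
LORENZ = "lorenz"

#: sign of a good score: +1 if higher is better (MC, VPT), -1 for RMSE
SCORE_SIGN = {MEMORY: 1.0, NARMA10: -1.0, MACKEY_GLASS: 1.0, LORENZ: 1.0}

#: mean of each task's input distribution, used by the designed rescaling
TASK_MEAN_INPUT = {MEMORY: 0.5, NARMA10: 0.25, MACKEY_GLASS: 0.5, LORENZ: 0.5}

#: sampling step in seconds (dimensionless for the discrete tasks)
TASK_DT = {MEMORY: 1.0, NARMA10: 1.0, MACKEY_GLASS: 0.1, LORENZ: 0.02}

DEFAULT_BETA_GRID = tuple(np.arange(-3.0, 1.01, 0.5))
DEFAULT_THETA_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)
DEFAULT_RHO_GRID = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class SweepSpec:
    """Grid specification for :func:`sweep_balance_threshold`."""

    beta_values: tuple = DEFAULT_BETA_GRID
    theta_values: tuple = DEFAULT_THETA_GRID
    task: str = MEMORY
    reps: int = 10
    seed: int = 0
    config: ReservoirConfig = field(default_factory=ReservoirConfig)
    split: SplitSpec | None = None


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit integer seeds derived from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# single-task evaluation
# ---------------------------------------------------------------------------

def evaluate_memory_task(
    conn: EIConnectivity,
    config: ReservoirConfig,
    rng_seed: int,
    split: SplitSpec | None = None,
    d_max: int = 70,
    return_details: bool = False,
):
    """Memory capacity of one reservoir realization.

    Drives the reservoir with i.i.d. uniform [0, 1] input, trains one
    ridge readout per delay d = 1..d_max on the shared state matrix, and
    sums the test-set R^2 over delays.
    """
    split = split or SplitSpec(washout=200, train=2500, test=1000)
    if split.washout < d_max:
        raise ValueError("washout must cover the largest delay")
    u = gen_uniform_input(split.total, 0.0, 1.0, rng_seed)
    train_states, test_states = harvest_states(
        conn, u, config.threshold, config.sigmoid_steepness, config.leakage, split
    )
    t_train = np.arange(split.washout, split.washout + split.train)
    targets = np.column_stack([u[t_train - d] for d in range(1, d_max + 1)])
    model = fit_ridge_readout(train_states, targets, config.ridge_penalty)
    preds = model.predict(test_states)
    mc, r2_curve = memory_capacity(u, preds, d_max)
    if return_details:
        return mc, r2_curve, test_states
    return mc


def evaluate_narma10_task(
    conn: EIConnectivity,
    config: ReservoirConfig,
    rng_seed: int,
    split: SplitSpec | None = None,
) -> float:
    """Open-loop NARMA-10 test RMSE of one reservoir realization."""
    split = split or SplitSpec(washout=200, train=2500, test=1000)
    u, y = gen_narma10(split.total, rng_seed=rng_seed)
    train_states, test_states = harvest_states(
        conn, u, config.threshold, config.sigmoid_steepness, config.leakage, split
    )
    y_train = y[split.washout : split.washout + split.train]
    y_test = y[split.washout + split.train : split.total]
    model = fit_ridge_readout(train_states, y_train, config.ridge_penalty)
    return rmse(y_test, model.predict(test_states)[:, 0])


def evaluate_chaotic_task(
    task: str,
    conn: EIConnectivity,
    config: ReservoirConfig,
    rng_seed: int,
    washout: int = 300,
    train: int = 3000,
    horizon: int = 1000,
    vpt_threshold: float = 0.4,
) -> float:
    """Closed-loop valid prediction time (seconds) on a chaotic series.

    Trains a one-step-ahead readout with teacher forcing, then lets the
    reservoir run autonomously and measures how long the forecast tracks
    the true trajectory. Per-repetition variability comes from perturbed
    initial conditions of the chaotic system.
    """
    rng = np.random.default_rng(rng_seed)
    total = washout + train
    if task == MACKEY_GLASS:
        series = integrate_mackey_glass(
            total + horizon + 1,
            MackeyGlassParams(),
            history_value=1.2 + 0.1 * rng.standard_normal(),
        )
    elif task == LORENZ:
        series, _ = integrate_lorenz(
            total + horizon + 1,
            LorenzParams(),
            initial_xyz=tuple(np.array([1.0, 1.0, 1.0]) + rng.normal(0.0, 0.5, 3)),
        )
    else:
        raise ValueError(f"not a chaotic task: {task!r}")
    split = SplitSpec(washout=washout, train=train, test=0)
    train_states, _ = harvest_states(
        conn, series[:total], config.threshold, config.sigmoid_steepness,
        config.leakage, split,
    )
    y_train = series[washout + 1 : total + 1]
    model = fit_ridge_readout(train_states, y_train, config.ridge_penalty)
    preds, _ = predict_closed_loop(
        conn, model, series[:total], horizon,
        config.threshold, config.sigmoid_steepness, config.leakage,
    )
    truth = series[total : total + len(preds)]
    return valid_prediction_time(truth, preds, TASK_DT[task], vpt_threshold).seconds


def evaluate_task(
    task: str,
    conn: EIConnectivity,
    config: ReservoirConfig,
    rng_seed: int,
    split: SplitSpec | None = None,
) -> float:
    """Dispatch to the task-specific evaluator; returns the raw score."""
    if task == MEMORY:
        return evaluate_memory_task(conn, config, rng_seed, split)
    if task == NARMA10:
        return evaluate_narma10_task(conn, config, rng_seed, split)
    if task in (MACKEY_GLASS, LORENZ):
        if split is not None:
            return evaluate_chaotic_task(
                task, conn, config, rng_seed, washout=split.washout, train=split.train
            )
        return evaluate_chaotic_task(task, conn, config, rng_seed)
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def sweep_balance_threshold(spec: SweepSpec) -> pd.DataFrame:
    """Characterize dynamics and performance over a (beta, theta) grid.

    For each cell: build a reservoir at that global balance, drive it with
    the memory-task input, and record mean firing rate, mean neuron
    entropy, memory capacity, and the regime label; cells are repeated
    over seeds and reported as mean with standard error. Failed cells are
    recorded as NaN with the failure reason.
    """
    split = spec.split or SplitSpec(washout=200, train=2500, test=1000)
    rows = []
    cell_seeds = _spawn_seeds(spec.seed, len(spec.beta_values) * len(spec.theta_values))
    idx = 0
    for beta in spec.beta_values:
        for theta in spec.theta_values:
            seeds = _spawn_seeds(cell_seeds[idx], spec.reps)
            idx += 1
            rates_, ents_, mcs_, regimes_ = [], [], [], []
            reason = ""
            for s in seeds:
                try:
                    cfg = spec.config.with_updates(balance=float(beta), threshold=float(theta))
                    conn = build_connectivity(cfg, rng_seed=s)
                    u = gen_uniform_input(split.total, 0.0, 1.0, s + 1)
                    from .dynamics import run

                    traj = run(conn, u, cfg.threshold, cfg.sigmoid_steepness, cfg.leakage)
                    post = traj.rates[split.washout :]
                    rates_.append(mean_rate(post))
                    ents_.append(
                        float(
                            np.mean(
                                [
                                    neuron_differential_entropy(post[:, i])
                                    for i in range(0, post.shape[1], 10)
                                ]
                            )
                        )
                    )
                    regimes_.append(classify_regime(post))
                    mcs_.append(evaluate_memory_task(conn, cfg, s + 2, split))
                except Exception as exc:  # noqa: BLE001 - cell failures become NaN rows
                    reason = f"{type(exc).__name__}: {exc}"
                    logger.warning("cell (beta=%s, theta=%s) failed: %s", beta, theta, reason)
            def _ms(vals):
                if not vals:
                    return np.nan, np.nan
                a = np.asarray(vals, dtype=float)
                a = a[np.isfinite(a)]
                if a.size == 0:
                    return np.nan, np.nan
                return a.mean(), a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
            rows.append(
                {
                    "beta": float(beta),
                    "theta": float(theta),
                    "mean_rate": _ms(rates_)[0],
                    "mean_rate_sem": _ms(rates_)[1],
                    "mean_entropy": _ms(ents_)[0],
                    "mean_entropy_sem": _ms(ents_)[1],
                    "memory_capacity": _ms(mcs_)[0],
                    "memory_capacity_sem": _ms(mcs_)[1],
                    "regime": max(set(regimes_), key=regimes_.count) if regimes_ else "failed",
                    "seeds": ",".join(map(str, seeds)),
                    "failure": reason,
                }
            )
    return pd.DataFrame(rows)


def best_global_tuning(
    task: str,
    beta_grid=DEFAULT_BETA_GRID,
    theta_grid=DEFAULT_THETA_GRID,
    sigma_in: float | None = None,
    reps: int = 5,
    config: ReservoirConfig | None = None,
    seed: int = 0,
    split: SplitSpec | None = None,
) -> tuple[float, float, float, pd.DataFrame]:
    """Exhaustive (beta, theta) grid search for the non-adaptive baseline.

    Returns (beta*, theta*, best mean score, full grid table); "best"
    maximizes MC/VPT or minimizes RMSE depending on the task.
    """
    if len(beta_grid) == 0 or len(theta_grid) == 0:
        raise ValueError("grids must be non-empty")
    config = config or ReservoirConfig()
    if sigma_in is not None:
        config = config.with_updates(input_spread=sigma_in)
    sign = SCORE_SIGN[task]
    rows = []
    cell_seeds = _spawn_seeds(seed, len(beta_grid) * len(theta_grid))
    idx = 0
    for beta in beta_grid:
        for theta in theta_grid:
            seeds = _spawn_seeds(cell_seeds[idx], reps)
            idx += 1
            scores = []
            for s in seeds:
                cfg = config.with_updates(balance=float(beta), threshold=float(theta))
                conn = build_connectivity(cfg, rng_seed=s)
                scores.append(evaluate_task(task, conn, cfg, s + 1, split))
            scores = np.asarray(scores, dtype=float)
            rows.append(
                {
                    "beta": float(beta),
                    "theta": float(theta),
                    "score": scores.mean(),
                    "sem": scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0,
                    "seeds": ",".join(map(str, seeds)),
                }
            )
    table = pd.DataFrame(rows)
    best = table.loc[(sign * table["score"]).idxmax()]
    return float(best["beta"]), float(best["theta"]), float(best["score"]), table


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

METHOD_NONADAPTIVE = "nonadaptive_tuned"
METHOD_ADAPTIVE_HOM = "adaptive_homogeneous"
METHOD_ADAPTIVE_HET = "adaptive_heterogeneous"
METHOD_DESIGNED_HOM = "designed_homogeneous"
METHOD_DESIGNED_HET = "designed_heterogeneous"
ALL_METHODS = (
    METHOD_NONADAPTIVE,
    METHOD_ADAPTIVE_HOM,
    METHOD_ADAPTIVE_HET,
    METHOD_DESIGNED_HOM,
    METHOD_DESIGNED_HET,
)


def _tuned_locally_balanced_scores(
    task: str,
    method: str,
    config: ReservoirConfig,
    seeds: list[int],
    rho_grid,
    adaptation_steps: int,
    beta_shape: float,
    split: SplitSpec | None,
) -> np.ndarray:
    """Scores of the adaptive/designed methods on matched seeds.

    Homogeneous variants tune rho_T over ``rho_grid`` (best mean across
    the matched seeds); heterogeneous variants use fixed Beta(a, a)
    targets, needing no tuning.
    """
    sign = SCORE_SIGN[task]
    heterogeneous = method in (METHOD_ADAPTIVE_HET, METHOD_DESIGNED_HET)
    designed = method in (METHOD_DESIGNED_HOM, METHOD_DESIGNED_HET)
    candidates = [None] if heterogeneous else list(rho_grid)
    best_scores = None
    for rho in candidates:
        scores = []
        for s in seeds:
            conn = build_connectivity(config, rng_seed=s)
            if heterogeneous:
                targets = sample_target_rates(
                    HETEROGENEOUS, config.n_neurons, beta_shape=beta_shape, rng_seed=s + 7
                )
            else:
                targets = sample_target_rates(HOMOGENEOUS, config.n_neurons, rho_T=rho)
            if designed:
                tuned = design_rescale(
                    conn, targets, TASK_MEAN_INPUT[task],
                    config.threshold, config.sigmoid_steepness,
                )
            else:
                tuned, _ = run_adaptation(
                    conn, config, targets, adaptation_steps, rng_seed=s + 13
                )
            scores.append(evaluate_task(task, tuned, config, s + 1, split))
        scores = np.asarray(scores, dtype=float)
        if best_scores is None or sign * scores.mean() > sign * best_scores.mean():
            best_scores = scores
    return best_scores


def run_comparison(
    task: str,
    methods=ALL_METHODS,
    reps: int = 5,
    seed: int = 0,
    config: ReservoirConfig | None = None,
    beta_grid=DEFAULT_BETA_GRID,
    theta_grid=DEFAULT_THETA_GRID,
    rho_grid=DEFAULT_RHO_GRID,
    adaptation_steps: int = 10_000,
    beta_shape: float = 5.0,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Compare tuning strategies on one task with matched seeds.

    The non-adaptive baseline is the best (beta, theta) grid cell; the
    locally tuned methods start from the balanced default configuration
    and are evaluated on the same seed list. Reports mean, SEM, and
    percent improvement over the baseline (positive = better: score
    increase for maximized metrics, decrease for RMSE).
    """
    config = config or ReservoirConfig()
    seeds = _spawn_seeds(seed, reps)
    results: list[tuple[str, np.ndarray]] = []
    baseline_info = {}
    base = None
    for method in methods:
        if method == METHOD_NONADAPTIVE:
            b, t, _, table = best_global_tuning(
                task, beta_grid, theta_grid, reps=reps, config=config,
                seed=seed + 1, split=split,
            )
            cfg = config.with_updates(balance=b, threshold=t)
            scores = np.asarray(
                [
                    evaluate_task(task, build_connectivity(cfg, rng_seed=s), cfg, s + 1, split)
                    for s in seeds
                ]
            )
            baseline_info = {"beta_star": b, "theta_star": t}
            base = scores.mean()
            results.append((method, scores))
        elif method in ALL_METHODS:
            results.append(
                (
                    method,
                    _tuned_locally_balanced_scores(
                        task, method, config, seeds, rho_grid, adaptation_steps,
                        beta_shape, split,
                    ),
                )
            )
        else:
            raise ValueError(f"unknown method {method!r}")

    rows = []
    for method, scores in results:
        row = {
            "task": task,
            "method": method,
            "mean": scores.mean(),
            "sem": scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0,
            "seeds": ",".join(map(str, seeds)),
        }
        if base is not None and method != METHOD_NONADAPTIVE:
            row["pct_improvement"] = percent_improvement(task, base, scores.mean())
        row.update(baseline_info if method == METHOD_NONADAPTIVE else {})
        rows.append(row)
    return pd.DataFrame(rows)


def percent_improvement(task: str, baseline: float, score: float) -> float:
    """Percent improvement of ``score`` over ``baseline`` for this task.

    For maximized metrics: 100*(score - baseline)/baseline; for RMSE the
    sign flips so that lower error is a positive improvement.
    """
    if baseline == 0:
        return float("nan")
    if SCORE_SIGN[task] > 0:
        return 100.0 * (score - baseline) / baseline
    return 100.0 * (baseline - score) / baseline


def input_scaling_sweep(
    task: str,
    sigma_in_grid,
    methods=(METHOD_NONADAPTIVE, METHOD_ADAPTIVE_HOM),
    reps: int = 5,
    seed: int = 0,
    config: ReservoirConfig | None = None,
    beta_grid=DEFAULT_BETA_GRID,
    theta_grid=DEFAULT_THETA_GRID,
    rho_grid=DEFAULT_RHO_GRID,
    adaptation_steps: int = 10_000,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Performance of each method as a function of input link scaling.

    For every sigma_in in the grid the baseline re-runs its (beta, theta)
    grid search and the adaptive/designed methods re-tune at that scaling;
    the table records mean and SEM per (sigma_in, method) cell.
    """
    if len(sigma_in_grid) == 0:
        raise ValueError("sigma_in grid must be non-empty")
    config = config or ReservoirConfig()
    frames = []
    for sigma_in in sigma_in_grid:
        cfg = config.with_updates(input_spread=float(sigma_in))
        table = run_comparison(
            task, methods, reps=reps, seed=seed, config=cfg,
            beta_grid=beta_grid, theta_grid=theta_grid, rho_grid=rho_grid,
            adaptation_steps=adaptation_steps, split=split,
        )
        table.insert(0, "sigma_in", float(sigma_in))
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
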