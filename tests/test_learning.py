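"""Ridge readout training and open/closed-loop evaluation."""

import numpy as np
import pytest

from eireservoir import (
    ReservoirConfig,
    SplitSpec,
    build_connectivity,
    fit_ridge_readout,
    harvest_states,
    predict_closed_loop,
    predict_open_loop,
    run,
)
from eireservoir.tasks import integrate_mackey_glass


def ridge_oracle(states, targets, eta):
    """Brute-force mean-centered normal equations for ridge regression."""
    Sm = states - states.mean(axis=0)
    Ym = targets - targets.mean(axis=0)
    W = np.linalg.solve(Sm.T @ Sm + eta * np.eye(states.shape[1]), Sm.T @ Ym)
    b = targets.mean(axis=0) - states.mean(axis=0) @ W
    return W, b


class TestRidgeReadout:
    def test_matches_normal_equations_oracle(self, rng):
        states = rng.random((50, 10))
        targets = rng.random((50, 3))
        eta = 1e-4
        model = fit_ridge_readout(states, targets, eta)
        W, b = ridge_oracle(states, targets, eta)
        assert np.abs(model.weights - W).max() / np.abs(W).max() < 1e-10
        assert np.allclose(model.intercept, b, atol=1e-10)

    def test_recovers_exact_linear_model(self, rng):
        states = rng.random((200, 8))
        true_w = rng.normal(0, 1, (8, 2))
        targets = states @ true_w + 3.0
        model = fit_ridge_readout(states, targets, 1e-10)
        assert np.abs(model.weights - true_w).max() < 1e-6
        assert np.allclose(model.intercept, 3.0, atol=1e-6)

    def test_infinite_penalty_shrinks_to_target_mean(self, rng):
        states = rng.random((100, 5))
        targets = rng.random(100)
        model = fit_ridge_readout(states, targets, 1e12)
        assert np.abs(model.weights).max() < 1e-6
        assert model.predict(states)[:, 0] == pytest.approx(targets.mean(), abs=1e-4)

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ridge_readout(rng.random((10, 2)), rng.random(10), -1.0)


class TestHarvestStates:
    def test_zero_washout_aligns_first_state_with_first_input(self, small_conn, small_config):
        u = np.random.default_rng(0).uniform(0, 1, 30)
        split = SplitSpec(washout=0, train=20, test=10)
        train, test = harvest_states(small_conn, u, 0.0, 10.0, 0.0, split)
        traj = run(small_conn, u, 0.0, 10.0)
        assert np.array_equal(train[0], traj.rates[0])
        assert train.shape == (20, 100) and test.shape == (10, 100)

    def test_states_bounded(self, small_conn):
        u = np.random.default_rng(1).uniform(0, 1, 40)
        train, test = harvest_states(small_conn, u, 0.0, 10.0, 0.0,
                                     SplitSpec(washout=5, train=25, test=10))
        assert train.min() >= 0.0 and test.max() <= 1.0

    def test_length_mismatch_rejected(self, small_conn):
        with pytest.raises(ValueError):
            harvest_states(small_conn, np.zeros(10), 0.0, 10.0, 0.0,
                           SplitSpec(washout=5, train=25, test=10))

    def test_zero_weight_reservoir_still_ridge_solvable(self):
        # constant state columns give a rank-deficient design; eta > 0 regularizes
        from eireservoir.connectivity import EXCITATORY, EIConnectivity

        n = 6
        conn = EIConnectivity(np.zeros((n, n)), np.zeros((n, n)), np.zeros(n),
                              np.array([EXCITATORY] * n))
        u = np.random.default_rng(2).uniform(0, 1, 30)
        train, _ = harvest_states(conn, u, 0.0, 10.0, 0.0,
                                  SplitSpec(washout=0, train=20, test=10))
        assert np.ptp(train, axis=0).max() == 0.0
        model = fit_ridge_readout(train, u[:20], 1e-7)
        assert np.isfinite(model.weights).all()


class TestLoops:
    def test_open_loop_deterministic(self, small_conn, small_config, rng):
        u = rng.uniform(0, 1, 100)
        model = fit_ridge_readout(
            harvest_states(small_conn, u, 0.0, 10.0, 0.0,
                           SplitSpec(washout=10, train=80, test=10))[0],
            u[10:90], 1e-7,
        )
        a = predict_open_loop(small_conn, model, u, 0.0, 10.0)
        b = predict_open_loop(small_conn, model, u, 0.0, 10.0)
        assert np.array_equal(a, b)

    def test_zero_horizon_gives_empty_forecast(self, small_conn):
        model = fit_ridge_readout(np.random.rand(20, 100), np.random.rand(20), 1e-7)
        preds, diverged = predict_closed_loop(small_conn, model, np.zeros(10), 0, 0.0, 10.0)
        assert len(preds) == 0 and not diverged

    def test_teacher_forcing_reproduces_open_loop(self, small_conn, rng):
        # feeding the true continuation back instead of predictions must give
        # exactly the open-loop outputs on that continuation
        series = rng.uniform(0, 1, 120)
        primer, future = series[:100], series[100:]
        states, _ = harvest_states(small_conn, series, 0.0, 10.0, 0.0,
                                   SplitSpec(washout=10, train=89, test=0))
        model = fit_ridge_readout(states, series[11:100], 1e-7)
        forced, _ = predict_closed_loop(small_conn, model, primer, 20, 0.0, 10.0,
                                        feedback_override=future)
        open_preds = predict_open_loop(small_conn, model, series, 0.0, 10.0)
        # forced[k] is the readout after consuming primer + future[:k]
        assert np.allclose(forced, open_preds[99:119, 0])

    def test_trained_mackey_glass_forecast_stays_on_attractor(self):
        cfg = ReservoirConfig(balance=-0.5)
        conn = build_connectivity(cfg, rng_seed=4)
        series = integrate_mackey_glass(3000)
        split = SplitSpec(washout=200, train=2500, test=0)
        states, _ = harvest_states(conn, series[:2700], cfg.threshold,
                                   cfg.sigmoid_steepness, cfg.leakage, split)
        model = fit_ridge_readout(states, series[201:2701], cfg.ridge_penalty)
        preds, diverged = predict_closed_loop(conn, model, series[:2700], 300,
                                              cfg.threshold, cfg.sigmoid_steepness)
        assert not diverged
        assert len(preds) == 300
        assert preds.min() > -0.2 and preds.max() < 1.2
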