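"""Rate-model dynamics: activation, integration, response norms, regimes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from schurnet.dynamics import (
    NetworkModel,
    SimulationDiverged,
    activation,
    classify_regime,
    linear_solution,
    max_response_norm,
    simulate,
    transient_duration,
)


class TestActivation:
    def test_zero_and_slope(self):
        assert activation(0.0) == 0.0
        # slope 1 at the origin (finite-difference oracle)
        h = 1e-6
        assert (activation(h) - activation(-h)) / (2 * h) == pytest.approx(1.0, abs=1e-6)
        assert activation(0.01) == pytest.approx(0.01, rel=1e-3)

    def test_saturation_bounds(self):
        assert activation(1e9) == pytest.approx(4.0)
        assert activation(-1e9) == pytest.approx(-1.0)

    def test_elementwise(self):
        x = np.array([-2.0, 0.0, 3.0])
        out = activation(x)
        assert out.shape == x.shape
        assert out[1] == 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            activation(np.nan)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_bounded_and_odd_signed(self, x):
        r = activation(x)
        assert -1.0 <= r <= 4.0
        assert r * x >= 0.0


class TestLinearDynamics:
    def test_pure_leak_decay(self):
        m = NetworkModel(W=np.zeros((3, 3)))
        x0 = np.array([1.0, 2.0, 2.0]) / 3.0
        traj = simulate(m, x0, duration=m.tau, dt=0.5, mode="linear")
        assert np.linalg.norm(traj.states[-1]) == pytest.approx(
            np.exp(-1.0) * np.linalg.norm(x0), rel=1e-8
        )

    def test_integrator_matches_closed_form(self, stable_random_w, rng):
        m = NetworkModel(W=stable_random_w)
        x0 = rng.normal(size=10)
        x0 /= np.linalg.norm(x0)
        traj = simulate(m, x0, duration=2000.0, dt=2.0, mode="linear")
        exact = linear_solution(m, x0, traj.times)
        scale = np.abs(exact.states).max()
        assert np.abs(traj.states - exact.states).max() / scale < 1e-6

    def test_linear_rates_equal_states(self, stable_random_w, rng):
        m = NetworkModel(W=stable_random_w)
        x0 = rng.normal(size=10)
        traj = simulate(m, x0, duration=200.0, mode="linear")
        assert np.array_equal(traj.states, traj.rates)

    def test_diagonal_closed_form(self):
        m = NetworkModel(W=0.5 * np.eye(4))
        x0 = np.ones(4)
        t = np.array([0.0, 100.0, 400.0])
        traj = linear_solution(m, x0, t)
        expect = np.exp(-0.5 * t / m.tau)
        assert np.allclose(traj.states[:, 0], expect, rtol=1e-12)

    def test_eigenvector_initialisation_stays_on_span(self, stable_random_w):
        m = NetworkModel(W=stable_random_w)
        lam, V = np.linalg.eig(stable_random_w)
        k = int(np.argmin(np.abs(lam.imag)))  # pick a (nearly) real mode
        v = np.real(V[:, k])
        v /= np.linalg.norm(v)
        traj = linear_solution(m, v, np.linspace(0, 1000, 11))
        # states remain multiples of v
        proj = traj.states - np.outer(traj.states @ v, v)
        assert np.abs(proj).max() < 1e-8

    def test_solution_norm_equals_direct_norm(self, stable_random_w, rng):
        # the eigen-decomposed solution reproduces the direct vector norm
        m = NetworkModel(W=stable_random_w)
        x0 = rng.normal(size=10)
        x0 /= np.linalg.norm(x0)
        times = np.linspace(0, 2000, 41)
        traj = linear_solution(m, x0, times)
        lam, V = np.linalg.eig(stable_random_w)
        coeff = np.linalg.solve(V, x0)
        direct = np.array(
            [
                np.linalg.norm(V @ (coeff * np.exp(t * (lam - 1) / m.tau)))
                for t in times
            ]
        )
        assert np.allclose(traj.norms(), direct, rtol=1e-9, atol=1e-12)

    def test_overflow_guard(self):
        m = NetworkModel(W=5.0 * np.eye(2))  # strongly unstable
        with pytest.raises(SimulationDiverged):
            simulate(m, np.ones(2), duration=50000.0, dt=2.0, mode="linear")


class TestNonlinearDynamics:
    def test_rates_bounded(self, stable_random_w, rng):
        m = NetworkModel(W=stable_random_w)
        x0 = 10.0 * rng.normal(size=10)
        traj = simulate(m, x0, duration=2000.0, mode="nonlinear")
        # open bounds mathematically; tanh reaches them only at float
        # saturation
        assert traj.rates.max() <= m.r_max
        assert traj.rates.min() >= -m.r_min

    def test_normal_stable_never_amplifies(self, rng):
        A = rng.normal(size=(8, 8))
        Wsym = 0.45 * (A + A.T) / np.abs(np.linalg.eigvalsh(A + A.T)).max()
        m = NetworkModel(W=Wsym)
        x0 = rng.normal(size=8)
        x0 /= np.linalg.norm(x0)
        traj = simulate(m, x0, duration=4000.0, mode="nonlinear")
        assert max_response_norm(traj) <= 1.0 + 1e-9

    def test_dt_convergence(self, stable_random_w, rng):
        m = NetworkModel(W=stable_random_w)
        x0 = rng.normal(size=10)
        x0 /= np.linalg.norm(x0)
        n2 = max_response_norm(simulate(m, x0, 2000.0, dt=2.0, mode="nonlinear"))
        n1 = max_response_norm(simulate(m, x0, 2000.0, dt=1.0, mode="nonlinear"))
        assert abs(n2 - n1) / n1 < 1e-3


class TestResponseMeasures:
    def test_max_norm_leak_is_initial(self):
        m = NetworkModel(W=np.zeros((4, 4)))
        x0 = np.full(4, 0.5)
        traj = simulate(m, x0, duration=1000.0, mode="linear")
        assert max_response_norm(traj) == pytest.approx(1.0)

    def test_feedforward_2x2_closed_form(self):
        # [[0, k], [0, 0]] from e2: x1(t) = (k t / tau) exp(-t/tau)
        k, tau = 10.0, 200.0
        m = NetworkModel(W=np.array([[0.0, k], [0.0, 0.0]]), tau=tau)
        traj = simulate(m, np.array([0.0, 1.0]), duration=4000.0, dt=1.0, mode="linear")
        peak = -minimize_scalar(
            lambda t: -np.hypot(k * t / tau, 1.0) * np.exp(-t / tau),
            bounds=(0.0, 4000.0),
            method="bounded",
        ).fun
        assert max_response_norm(traj) == pytest.approx(peak, rel=1e-5)
        assert max_response_norm(traj) > 1.0

    def test_transient_duration_leak_zero(self):
        m = NetworkModel(W=np.zeros((3, 3)))
        x0 = np.ones(3) / np.sqrt(3)
        traj = simulate(m, x0, duration=2000.0, mode="nonlinear")
        assert transient_duration(traj).delta_t == 0.0

    def test_transient_duration_censoring(self):
        m = NetworkModel(W=np.zeros((2, 2)))
        traj = simulate(m, np.array([3.0, 3.0]), duration=100.0, mode="linear")
        td = transient_duration(traj, threshold=1.0)
        assert td.censored and td.delta_t == pytest.approx(100.0)

    def test_duration_definitions_on_synthetic_trace(self):
        from schurnet.dynamics import Trajectory

        times = np.arange(7, dtype=float)
        norms = np.array([2.0, 2.0, 0.5, 2.0, 2.0, 0.5, 0.2])
        states = np.zeros((7, 2))
        states[:, 0] = norms
        traj = Trajectory(times=times, states=states, rates=states, mode="linear")
        last = transient_duration(traj, definition="last_crossing").delta_t
        total = transient_duration(traj, definition="total_above").delta_t
        assert last > total  # bridged dip counts only in last_crossing
        # super-threshold sample intervals: [0,2] and [3,5]
        assert total == pytest.approx(4.0)
        # final down-crossing interpolated between samples 4 (2.0) and 5 (0.5)
        assert last == pytest.approx(4.0 + 2.0 / 3.0)


class TestRegimes:
    @pytest.mark.parametrize(
        "delta_t,label",
        [
            (0.0, "weak"),
            (500.0, "weak"),
            (501.0, "short_transient"),
            (1000.0, "short_transient"),
            (2000.0, "long_transient"),
            (5000.0, "long_transient"),
        ],
    )
    def test_classification(self, delta_t, label):
        assert classify_regime(delta_t).label == label

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(-1.0)
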