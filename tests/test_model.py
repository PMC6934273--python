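"""Core adaptive coincidence counting model: exact update, spiking rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbcpop.model import (
    GBCParameters,
    SimulationConfig,
    SpikeData,
    simulate_gbc,
    threshold_trace,
    update_threshold,
)
from conftest import make_spikes


def euler_oracle(theta0, v, t_a, s_a, horizon, n_sub):
    """Fine-step explicit Euler integration of t_a*dth/dt = -th + s_a*v."""
    h = horizon / n_sub
    th = theta0
    for _ in range(n_sub):
        th = th + h * (-th + s_a * v) / t_a
    return th


class TestUpdateThreshold:
    def test_zero_fixed_point(self):
        assert update_threshold(0.0, 0.0, t_a=0.25, s_a=0.8, dt=0.01) == 0.0

    @pytest.mark.parametrize("v", [0.0, 0.4, 1.2, 3.0])
    def test_steady_state_invariant(self, v):
        s_a = 0.8
        th = s_a * v
        assert update_threshold(th, v, t_a=0.25, s_a=s_a, dt=0.01) == pytest.approx(
            th, rel=1e-14)

    def test_single_step_matches_fine_euler(self):
        got = update_threshold(0.0, 1.0, t_a=0.25, s_a=0.8, dt=0.01)
        assert got == pytest.approx((1.0 - np.exp(-0.04)) * 0.8, rel=1e-12)
        oracle = euler_oracle(0.0, 1.0, t_a=0.25, s_a=0.8, horizon=0.01,
                              n_sub=100_000)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_iterated_update_matches_closed_form(self):
        # n steps at constant v equal the exponential relaxation at n*dt.
        t_a, s_a, dt, v = 0.3, 1.1, 0.01, 2.0
        th = 0.7
        n = 500
        for _ in range(n):
            th = update_threshold(th, v, t_a, s_a, dt)
        closed = s_a * v + (0.7 - s_a * v) * np.exp(-n * dt / t_a)
        assert th == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize("t_a,dt", [(0.0, 0.01), (-1.0, 0.01), (0.25, 0.0)])
    def test_invalid_parameters(self, t_a, dt):
        with pytest.raises(ValueError):
            update_threshold(0.0, 1.0, t_a=t_a, s_a=0.8, dt=dt)

    @given(theta0=st.floats(0, 5), v=st.floats(0, 5),
           t_a=st.floats(0.05, 1.0), s_a=st.floats(0, 2))
    @settings(max_examples=50, derandomize=True)
    def test_moves_toward_equilibrium(self, theta0, v, t_a, s_a):
        new = update_threshold(theta0, v, t_a, s_a, dt=0.01)
        eq = s_a * v
        assert abs(new - eq) <= abs(theta0 - eq) + 1e-12


class TestThresholdTrace:
    def test_matches_stepwise_update(self, rng):
        v = rng.random(200) * 3
        t_a, s_a = 0.2, 0.9
        trace = threshold_trace(v, t_a, s_a, dt=0.01, initial=0.5)
        th, ref = 0.5, []
        for j in range(v.size):
            ref.append(th)
            th = update_threshold(th, v[j], t_a, s_a, 0.01)
        assert np.allclose(trace, ref, rtol=1e-12, atol=1e-14)


PARAMS = GBCParameters(m_e=3, w_e=0.32, a_e=0.4, t_r=1.2, t_a=0.25, s_a=0.8)
CFG = SimulationConfig(dt=0.01, duration=10.0)


class TestSimulateGBC:
    def test_no_input_no_output(self):
        inputs = [make_spikes([[]], duration=10.0) for _ in range(3)]
        out = simulate_gbc(inputs, PARAMS, CFG)
        assert out.n_spikes == 0

    def test_synchronized_volley_spikes_at_volley_time(self):
        # Three coincident inputs: v jumps to 1.2 >= theta = 1.0 at 1.00 ms.
        inputs = [make_spikes([[1.00]], duration=10.0) for _ in range(3)]
        out = simulate_gbc(inputs, PARAMS, CFG)
        assert out.n_spikes == 1
        assert out.trials[0][0] == pytest.approx(1.00)

    def test_asynchronous_inputs_subthreshold(self):
        # Single spikes far apart: v never exceeds a_e = 0.4 < 1.
        times = [[1.0], [3.0], [5.0]]
        inputs = [make_spikes([t], duration=10.0) for t in times]
        out = simulate_gbc(inputs, PARAMS, CFG)
        assert out.n_spikes == 0

    def test_second_volley_inside_refractory_suppressed(self):
        # Volleys at 1.0 and 1.5 ms; t_r = 1.2 ms blocks the second.
        inputs = [make_spikes([[1.0, 1.5]], duration=10.0) for _ in range(3)]
        out = simulate_gbc(inputs, PARAMS, CFG)
        assert out.n_spikes == 1
        assert out.trials[0][0] == pytest.approx(1.0)

    def test_wrong_fiber_count_raises(self):
        inputs = [make_spikes([[1.0]], duration=10.0) for _ in range(2)]
        with pytest.raises(ValueError, match="fibers"):
            simulate_gbc(inputs, PARAMS, CFG)

    def test_spike_outside_trial_raises(self):
        inputs = [make_spikes([[12.0]], duration=10.0) for _ in range(3)]
        with pytest.raises(ValueError):
            simulate_gbc(inputs, PARAMS, CFG)


def poisson_inputs(rng, m_e, n_trials=20, duration=50.0, rate=300.0):
    fibers = []
    for _ in range(m_e):
        trials = []
        for _ in range(n_trials):
            n = rng.poisson(rate * duration / 1000.0)
            trials.append(np.sort(rng.random(n)) * duration)
        fibers.append(make_spikes(trials, duration=duration))
    return fibers


class TestSimulationProperties:
    def setup_method(self):
        rng = np.random.default_rng(777)
        self.params = GBCParameters(m_e=10, w_e=0.32, a_e=0.4, t_r=1.2,
                                    t_a=0.25, s_a=0.8)
        self.cfg = SimulationConfig(dt=0.01, duration=50.0)
        self.inputs = poisson_inputs(rng, self.params.m_e, duration=50.0)

    def test_refractoriness(self):
        out = simulate_gbc(self.inputs, self.params, self.cfg)
        assert out.n_spikes > 0
        out.validate(min_isi=self.params.t_r - self.cfg.dt / 2)

    def test_output_count_bounded_by_refractory(self):
        out = simulate_gbc(self.inputs, self.params, self.cfg)
        cap = int(self.cfg.duration / self.params.t_r) + 1
        assert max(t.size for t in out.trials) <= cap

    def test_output_steps_have_active_input(self):
        # With rectangular inputs, every output step must see v > 0.
        from gbcpop.model import bin_input_counts, windowed_counts, quantize_steps
        out = simulate_gbc(self.inputs, self.params, self.cfg)
        counts = bin_input_counts(self.inputs, self.cfg.dt, self.cfg.n_steps)
        w = quantize_steps(self.params.w_e, self.cfg.dt, minimum=1)
        wsum = windowed_counts(counts, w)
        for trial, spikes in enumerate(out.trials):
            idx = np.floor(spikes / self.cfg.dt + 0.5).astype(int)
            assert np.all(wsum[trial, idx] > 0)

    def test_adaptation_only_removes_spikes(self):
        out_adapt = simulate_gbc(self.inputs, self.params, self.cfg)
        no_adapt = GBCParameters(**{**self.params.as_dict(), "s_a": 0.0})
        out_free = simulate_gbc(self.inputs, no_adapt, self.cfg)
        for a, b in zip(out_adapt.trials, out_free.trials):
            assert b.size >= a.size

    def test_determinism(self):
        a = simulate_gbc(self.inputs, self.params, self.cfg)
        b = simulate_gbc(self.inputs, self.params, self.cfg)
        for x, y in zip(a.trials, b.trials):
            assert np.array_equal(x, y)


class TestParameterValidation:
    @pytest.mark.parametrize("kw", [
        {"m_e": 0}, {"w_e": 0.0}, {"a_e": -0.1}, {"t_r": -1.0},
        {"t_a": 0.0}, {"s_a": -0.5},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            GBCParameters(**{**GBCParameters().as_dict(), **kw})

    def test_spike_data_validation(self):
        bad = SpikeData(trials=[np.array([3.0, 2.0])], trial_duration=10.0)
        with pytest.raises(ValueError, match="increasing"):
            bad.validate()
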