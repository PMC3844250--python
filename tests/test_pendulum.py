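"""Inverted-pendulum dynamics, delayed feedback, and preflex behaviour."""
import math

import numpy as np
import pytest

from hillmuscle.errors import DomainError
from hillmuscle.pendulum_control import (ControllerConfig, DelayBuffer,
                                         PendulumParams, PerturbationSpec,
                                         actuator_torque, delayed_signal,
                                         gravity_torque, perturbation_angle,
                                         simulate)

DEG = math.pi / 180.0


class TestPerturbation:
    @pytest.mark.parametrize("t, expected_deg", [(0.0, 0.0), (0.5, 0.5),
                                                 (1.0, 1.0), (2.0, 1.0)])
    def test_ramp_saturates(self, t, expected_deg):
        a, _ = perturbation_angle(t, PerturbationSpec.ramp())
        assert a == pytest.approx(expected_deg * DEG)

    def test_sine_quarter_period(self):
        a, adot = perturbation_angle(0.25, PerturbationSpec.sine_1hz())
        assert a == pytest.approx(1.0 * DEG)
        assert adot == pytest.approx(0.0, abs=1e-12)

    def test_slow_sine_frequency(self):
        a, _ = perturbation_angle(2.5, PerturbationSpec.sine_01hz())
        assert a == pytest.approx(math.sin(0.5 * math.pi) * DEG, rel=1e-12)

    def test_none_is_zero(self):
        assert perturbation_angle(1.0, None) == (0.0, 0.0)


class TestGravity:
    def test_upright_and_one_degree(self):
        p = PendulumParams()
        assert gravity_torque(0.0, p) == 0.0
        assert gravity_torque(1.0 * DEG, p) == pytest.approx(8.132, abs=1e-3)
        assert gravity_torque(-0.2, p) == -gravity_torque(0.2, p)


class TestDelay:
    def test_zero_delay_is_identity(self):
        buf = [0.1, 0.2, 0.3]
        assert delayed_signal(buf, 0.002, 0.001, 0.0) == 0.3

    def test_constant_signal(self):
        buf = [5.0] * 10
        assert delayed_signal(buf, 0.009, 0.001, 0.004) == 5.0

    def test_step_observed_after_dead_time(self):
        dt = 0.001
        buf = DelayBuffer(dt)
        # unit step at t = 0.2, sampled to 0.4
        buf.samples = [0.0 if k * dt < 0.2 else 1.0 for k in range(401)]
        assert buf.read(0.299, 0.1) == 0.0
        assert buf.read(0.301, 0.1) == 1.0

    def test_non_multiple_delay_warns(self):
        with pytest.warns(UserWarning, match="nearest"):
            delayed_signal([1.0, 2.0], 0.001, 0.001, 0.0015)


class TestActuatorTorque:
    def test_symmetric_muscles_zero_torque(self):
        p = PendulumParams()
        from hillmuscle.mtu import equilibrium_l_mtu
        l_ce = p.l_CE_init_rel * p.mtu.l_CE_opt
        l_ref = equilibrium_l_mtu(l_ce, p.q0, p.mtu)
        tau = actuator_torque(p, ControllerConfig(), 0.0, 0.0, 0.0, 0.0, 0.0,
                              l_ref=l_ref, l_CE_pair=(l_ce, l_ce),
                              q_pair=(p.q0, p.q0))
        assert tau == pytest.approx(0.0, abs=1e-9)

    def test_torque_mode_gain_times_radian_error(self):
        p = PendulumParams(actuator="torque")
        cfg = ControllerConfig(mode="P", Kp=500.0)
        pid = cfg.Kp * (1.0 * DEG)
        tau = actuator_torque(p, cfg, pid, 0.0, 0.0, 0.0, 0.0)
        assert abs(tau) == pytest.approx(8.727, abs=1e-3)

    def test_preflex_opposes_ground_step(self):
        """With no feedback, tilting the foot immediately produces a torque
        of opposing sign through the muscles' stretch."""
        p = PendulumParams()
        from hillmuscle.mtu import equilibrium_l_mtu
        l_ce = p.l_CE_init_rel * p.mtu.l_CE_opt
        l_ref = equilibrium_l_mtu(l_ce, p.q0, p.mtu)
        # foot steps to +1 deg (beta still 0): relative angle beta - alpha < 0
        tau = actuator_torque(p, ControllerConfig(), 0.0, 0.0, 0.0, 1.0 * DEG,
                              0.0, l_ref=l_ref, l_CE_pair=(l_ce, l_ce),
                              q_pair=(p.q0, p.q0))
        assert tau > 0.0  # pushes beta toward the new foot orientation


class TestSimulate:
    def test_no_gravity_no_actuator_stays_put(self):
        p = PendulumParams(actuator="none", g=0.0, beta0_deg=0.0)
        res = simulate(p, None, duration=0.5)
        assert np.all(res.beta == 0.0)

    def test_determinism_bit_identical(self):
        p = PendulumParams()
        cfg = ControllerConfig.preset("muscles", "P")
        r1 = simulate(p, PerturbationSpec.sine_1hz(), cfg, duration=1.0)
        r2 = simulate(p, PerturbationSpec.sine_1hz(), cfg, duration=1.0)
        assert np.array_equal(r1.beta, r2.beta)
        assert np.array_equal(r1.tau, r2.tau)

    def test_passive_energy_conservation(self):
        """Undriven pendulum: total mechanical energy drifts only at the
        integrator's O(dt^5)-per-step level over a full swing."""
        p = PendulumParams(actuator="none", beta0_deg=10.0, topple_deg=180.0)
        res = simulate(p, None, duration=2.0)
        # beta measured from inverted vertical: COG height = h cos(beta)
        E = (0.5 * p.J * np.gradient(res.beta, res.t) ** 2
             + p.m * p.g * p.h_COG * np.cos(res.beta))
        # gradient() itself is only O(dt^2); compare start/end via states
        omega_end = (res.beta[-1] - res.beta[-3]) / (res.t[-1] - res.t[-3])
        E0 = p.m * p.g * p.h_COG * math.cos(res.beta[0])
        E1 = (0.5 * p.J * omega_end ** 2
              + p.m * p.g * p.h_COG * math.cos(res.beta[-1]))
        assert E1 == pytest.approx(E0, rel=1e-5)

    def test_passive_growth_matches_linearised_eigenvalue(self):
        from hillmuscle.pendulum_control import passive_growth_rate
        lam = passive_growth_rate()
        assert lam == pytest.approx(math.sqrt(9.81 / 0.95), rel=5e-3)

    def test_muscle_preflex_bounded_short_run(self):
        res = simulate(PendulumParams(), PerturbationSpec.ramp(),
                       ControllerConfig(), duration=3.0)
        assert not res.toppled
        assert np.max(np.abs(res.beta)) < 5 * DEG

    def test_torque_without_feedback_diverges(self):
        res = simulate(PendulumParams(actuator="torque"),
                       PerturbationSpec.ramp(), ControllerConfig(),
                       duration=4.0)
        assert res.toppled

    def test_invalid_duration(self):
        with pytest.raises(DomainError):
            simulate(PendulumParams(actuator="none"), None, duration=-1.0)


class TestConfigs:
    def test_presets_match_published_gains(self):
        t = ControllerConfig.preset("torque", "PID")
        assert (t.Kp, t.Ki, t.Kd) == (500.0, 50.0, 500.0)
        m = ControllerConfig.preset("muscles", "PID")
        assert (m.Kp, m.Ki, m.Kd) == (1.0, 0.3, 0.3)
        assert t.delay == m.delay == 0.1

    def test_default_inertia_consistent_with_point_mass(self):
        p = PendulumParams()
        assert p.J == pytest.approx(p.m * p.h_COG ** 2)

    @pytest.mark.parametrize("kw", [
        {"m": -1.0}, {"actuator": "rocket"}, {"q0": 2.0},
    ])
    def test_invalid_params(self, kw):
        with pytest.raises(DomainError):
            PendulumParams(**kw)
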