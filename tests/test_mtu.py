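"""Muscle-tendon-unit model: force elements, contraction rate, activation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from hillmuscle import fit_hyperbola
from hillmuscle.errors import DomainError
from hillmuscle.fvcurve import FVCurve
from hillmuscle.mtu import (MTUParams, MTUState, activation_rate, ce_force,
                            contraction_rate, equilibrium_l_mtu,
                            isometric_force_length, mtu_force, pee_force,
                            see_force, see_length_at_force, see_stiffness)


class TestForceLength:
    def test_optimum_and_bell_width(self, tibialis):
        p = tibialis
        assert isometric_force_length(p.l_CE_opt, p) == 1.0
        assert isometric_force_length(p.l_CE_opt * (1 + p.dW), p) == \
            pytest.approx(math.exp(-1))

    @given(x=st.floats(0.01, 0.8))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x):
        p = MTUParams()
        up = isometric_force_length(p.l_CE_opt * (1 + x), p)
        dn = isometric_force_length(p.l_CE_opt * (1 - x), p)
        assert up == pytest.approx(dn, rel=1e-12)


class TestSerialElastic:
    def test_slack_below_rest_length(self, tibialis):
        assert see_force(0.9 * tibialis.l_SEE0, tibialis) == 0.0
        assert see_force(tibialis.l_SEE0, tibialis) == 0.0

    def test_c1_continuity_at_toe_junction(self, tibialis):
        p = tibialis
        l_junc = p.l_SEE0 * (1 + p.dU_SEE_nll)
        assert see_force(l_junc - 1e-12, p) == pytest.approx(
            see_force(l_junc + 1e-12, p), rel=1e-9)
        assert see_stiffness(l_junc - 1e-12, p) == pytest.approx(
            see_stiffness(l_junc + 1e-12, p), rel=1e-9)
        assert see_force(l_junc, p) == pytest.approx(p.dF_SEE0, rel=1e-12)

    def test_linear_region_stiffness(self, tibialis):
        p = tibialis
        k_expected = p.dF_SEE0 / (p.dU_SEE_l * p.l_SEE0)  # 595,593 N/m
        assert p.k_SEE_linear == pytest.approx(k_expected)
        assert see_stiffness(p.l_SEE0 * 1.3, p) == pytest.approx(k_expected)

    @given(F=st.floats(0.0, 3e4))
    @settings(max_examples=60, deadline=None)
    def test_force_length_inverse(self, F):
        p = MTUParams()
        assert see_force(see_length_at_force(F, p), p) == pytest.approx(
            F, abs=1e-6 * p.F_max)


class TestForceVelocity:
    def test_isometric_and_characteristic_speeds(self, tibialis):
        p = tibialis
        assert ce_force(p.l_CE_opt, 0.0, 1.0, p) == pytest.approx(p.F_max)
        assert ce_force(p.l_CE_opt, 0.0, 0.4, p) == pytest.approx(0.4 * p.F_max)
        # unloaded shortening velocity B_rel0 l_opt / A_rel0 = 0.9 m/s
        assert ce_force(p.l_CE_opt, -0.9, 1.0, p) == pytest.approx(0.0, abs=1e-9)
        # half the isometric force at 0.15 m/s shortening
        assert ce_force(p.l_CE_opt, -0.15, 1.0, p) == pytest.approx(0.5 * p.F_max)

    def test_eccentric_slope_ratio_and_asymptote(self, tibialis):
        p = tibialis
        h = 1e-7
        con = (ce_force(p.l_CE_opt, 0.0, 1.0, p)
               - ce_force(p.l_CE_opt, -h, 1.0, p)) / h
        ecc = (ce_force(p.l_CE_opt, h, 1.0, p)
               - ce_force(p.l_CE_opt, 0.0, 1.0, p)) / h
        assert ecc / con == pytest.approx(p.ecc_slope_factor, rel=1e-4)
        assert ce_force(p.l_CE_opt, 10.0, 1.0, p) < p.ecc_force_factor * p.F_max
        assert ce_force(p.l_CE_opt, 10.0, 1.0, p) > 1.4 * p.F_max


class TestContractionRate:
    def test_equilibrium_gives_zero_rate(self, tibialis):
        for l_rel, q in [(1.05, 0.1), (0.95, 0.5), (1.0, 1.0)]:
            l_ce = l_rel * tibialis.l_CE_opt
            lm = equilibrium_l_mtu(l_ce, q, tibialis)
            st_ = MTUState(l_CE=l_ce, q=q, l_MTU=lm, v_MTU=0.0)
            assert contraction_rate(st_, tibialis) == pytest.approx(0.0, abs=1e-12)

    def test_max_serial_damping_scale(self, tibialis):
        p = tibialis
        assert p.d_SE_max == pytest.approx(
            p.D_SE * p.F_max * p.A_rel0 / (p.l_CE_opt * p.B_rel0))
        assert p.d_SE_max == pytest.approx(3333.3, abs=0.1)

    @given(l_rel=st.floats(0.7, 1.3), q=st.floats(0.0, 1.0),
           dl=st.floats(-0.01, 0.01), v=st.floats(-0.3, 0.3))
    @settings(max_examples=150, deadline=None)
    def test_balance_residual(self, l_rel, q, dl, v):
        """The returned rate satisfies the series force equilibrium to
        1e-6 F_max for arbitrary (perturbed) states."""
        p = MTUParams()
        l_ce = l_rel * p.l_CE_opt
        lm = equilibrium_l_mtu(l_ce, max(q, 1e-3), p) + dl
        st_ = MTUState(l_CE=l_ce, q=q, l_MTU=lm, v_MTU=v)
        x = contraction_rate(st_, p)
        F_ce = ce_force(l_ce, x, q, p)
        F_pee = pee_force(l_ce, p)
        d = p.d_SE_max * ((1 - p.R_SE) * (F_ce + F_pee) / p.F_max + p.R_SE)
        lhs = see_force(lm - l_ce, p) + d * (v - x)
        assert lhs == pytest.approx(F_ce + F_pee, abs=1e-6 * p.F_max)

    def test_stretch_step_relaxes_monotonically(self, tibialis):
        """A step increase of the path length at constant activation gives a
        lengthening CE and a force overshoot that decays monotonically."""
        p = tibialis
        l_ce = 1.05 * p.l_CE_opt
        lm = equilibrium_l_mtu(l_ce, 0.1, p)
        F_eq = mtu_force(MTUState(l_CE=l_ce, q=0.1, l_MTU=lm), p)
        lm2 = lm + 0.002
        dt = 1e-3
        forces, l = [], l_ce
        for _ in range(400):
            st_ = MTUState(l_CE=l, q=0.1, l_MTU=lm2, v_MTU=0.0)
            x = contraction_rate(st_, p)
            forces.append(ce_force(l, x, 0.1, p) + pee_force(l, p))
            l += x * dt
        assert forces[0] > F_eq                      # overshoot
        assert np.all(np.diff(forces) <= 1e-9)       # monotone decay
        assert forces[-1] > F_eq                     # to a stiffer equilibrium

    def test_quick_release_recovers_normalised_hill_a(self, tibialis):
        """Concentric operating points against constant loads fit a
        hyperbola whose a_rel is within 5% of A_rel0."""
        p = tibialis
        l_ce = 0.9 * p.l_CE_opt  # below the PEE slack length: pure CE curve
        assert pee_force(l_ce, p) == 0.0
        F0 = p.F_max * isometric_force_length(l_ce, p)
        loads = np.linspace(0.05, 0.9, 12) * F0

        def v_at(Fl):
            f = lambda x: ce_force(l_ce, x, 1.0, p) - Fl
            return -brentq(f, -0.9, 0.0)

        curve = FVCurve.from_arrays(loads, [v_at(F) for F in loads])
        fit = fit_hyperbola(curve, P0_mode="fixed", P0=F0)
        assert fit.constants.a / p.F_max == pytest.approx(p.A_rel0, rel=0.05)


class TestActivation:
    def test_fixed_point(self, tibialis):
        assert activation_rate(0.4, 0.4, tibialis) == 0.0

    def test_exponential_closed_form(self, tibialis):
        p = tibialis
        q, u, dt = 0.1, 0.8, 1e-4
        for _ in range(int(0.1 / dt)):
            q += activation_rate(q, u, p) * dt
        expected = u + (0.1 - u) * math.exp(-0.1 / p.tau_act)
        assert q == pytest.approx(expected, rel=1e-3)

    def test_small_tau_approaches_instant(self):
        p = MTUParams(tau_act=1e-4)
        q, u = 0.0, 0.7
        dt = 1e-5
        for _ in range(2000):
            q += activation_rate(q, u, p) * dt
        assert q == pytest.approx(u, abs=1e-6)
        assert activation_rate(0.3, 0.9, MTUParams(tau_act=None)) == 0.0

    def test_domain(self, tibialis):
        with pytest.raises(DomainError):
            activation_rate(0.5, 1.5, tibialis)
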