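"""Inverted-pendulum postural benchmark with delayed feedback.

A single rigid leg/trunk segment S1 (mass m, inertia J about the hinge,
centre of gravity at height h_COG) balances on a hinge above a massless,
kinematically driven foot S2.  The foot angle alpha(t) is the perturbation;
beta is the deviation of S1 from vertical (the controlled variable).  The
hinge is actuated either by

* a **direct torque generator** — commands the PID torque directly, or
* an **antagonistic pair of muscle-tendon units** — the joint angle drives
  the MTU path lengths (l = l_ref +/- r_m * (beta - alpha)), so ground
  motion perturbs the muscles mechanically even with no feedback at all;
  this intrinsic, zero-delay response is the *preflex*.  Feedback acts by
  shifting the stimulation of the pair around a co-activation baseline q0.

The feedback signal is beta delayed by a physiological dead time (default
0.1 s).  Integration is fixed-step 5th-order Dormand-Prince at 1 ms, which
keeps the delay an exact integer number of steps.

Default muscle geometry (the benchmark leaves it open; values fixed by
linearised stability analysis and logged in every result): moment arm
r_m = 0.15 m, both CEs at 1.05 * l_CE_opt at beta = alpha = 0 — slightly
past optimum so the parallel elastic elements are engaged — at co-activation
q0 = 0.1.  This places the static joint stiffness of the antagonistic pair
well above the gravitational destabilising stiffness m g h_COG (preflex
stability without any feedback) and keeps the pair's intrinsic joint damping
(which scales with r_m^2) above the negative damping that the delayed P
feedback (which scales with r_m) injects near the co-activated resonance.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mtu as mtu_mod
from .errors import DomainError
from .mtu import MTUParams, _contraction_rate

__all__ = [
    "PendulumParams", "PerturbationSpec", "ControllerConfig", "DelayBuffer",
    "SimulationResult", "perturbation_angle", "gravity_torque",
    "actuator_torque", "delayed_signal", "simulate", "passive_growth_rate",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class PendulumParams:
    """Segment, actuator and muscle-geometry settings.

    Defaults: m = 50 kg, J = 45.125 kg m^2 (about the hinge), h_COG = 0.95 m
    (so J = m h^2 exactly), g = 9.81 m/s^2.  ``actuator`` is "torque",
    "muscles" or "none" (passive).  ``beta0_deg`` seeds the otherwise
    perfectly balanced pendulum; ``topple_deg`` is the (heuristic) angle
    beyond which the run is declared toppled.
    """

    m: float = 50.0
    J: float = 45.125
    h_COG: float = 0.95
    g: float = 9.81
    actuator: str = "muscles"
    r_m: float = 0.15
    l_CE_init_rel: float = 1.05
    q0: float = 0.1
    beta0_deg: float = 0.1
    topple_deg: float = 30.0
    mtu: MTUParams = field(default_factory=MTUParams)

    def __post_init__(self):
        if self.m <= 0 or self.J <= 0 or self.h_COG <= 0:
            raise DomainError("m, J, h_COG must be positive")
        if self.actuator not in ("torque", "muscles", "none"):
            raise DomainError(f"unknown actuator {self.actuator!r}")
        if self.actuator == "muscles":
            if self.r_m <= 0:
                raise DomainError("moment arm r_m must be positive")
            if not 0.0 <= self.q0 <= 1.0:
                raise DomainError("q0 must lie in [0, 1]")


@dataclass(frozen=True)
class PerturbationSpec:
    """Foot-angle protocol: a saturating ramp or a sinusoid.

    The three published protocols: ramp at 1 deg/s saturating at 1 deg;
    1 deg sinusoids at 1 Hz and at 0.1 Hz.
    """

    kind: str = "ramp"
    amplitude_deg: float = 1.0
    rate_dps: float = 1.0    # ramp slope [deg/s]
    freq_hz: float = 1.0     # sine frequency

    def __post_init__(self):
        if self.kind not in ("ramp", "sine"):
            raise DomainError(f"unknown perturbation kind {self.kind!r}")

    @classmethod
    def ramp(cls) -> "PerturbationSpec":
        return cls(kind="ramp", amplitude_deg=1.0, rate_dps=1.0)

    @classmethod
    def sine_1hz(cls) -> "PerturbationSpec":
        return cls(kind="sine", amplitude_deg=1.0, freq_hz=1.0)

    @classmethod
    def sine_01hz(cls) -> "PerturbationSpec":
        return cls(kind="sine", amplitude_deg=1.0, freq_hz=0.1)


@dataclass(frozen=True)
class ControllerConfig:
    """Feedback settings: mode "none" | "P" | "PID", gains, dead time.

    Torque-generator gains map radians of error to N m; muscle gains map
    radians to differential stimulation.  The integral term is clamped
    (anti-windup) so |Ki * I| never exceeds ``integral_clamp`` in the
    actuator's output units.
    """

    mode: str = "none"
    Kp: float = 0.0
    Ki: float = 0.0
    Kd: float = 0.0
    delay: float = 0.1
    integral_clamp: float = math.inf

    def __post_init__(self):
        if self.mode not in ("none", "P", "PID"):
            raise DomainError(f"unknown controller mode {self.mode!r}")
        if self.delay < 0:
            raise DomainError("delay must be >= 0")
        if min(self.Kp, self.Ki, self.Kd) < 0:
            raise DomainError("gains must be >= 0")

    @classmethod
    def preset(cls, actuator: str, mode: str) -> "ControllerConfig":
        """Published gain sets: torque P 500 / PID 500, 50, 500;
        muscles P 1 / PID 1, 0.3, 0.3 (delay 0.1 s)."""
        if mode == "none":
            return cls(mode="none")
        if actuator == "torque":
            gains = {"P": (500.0, 0.0, 0.0), "PID": (500.0, 50.0, 500.0)}
            clamp = 1000.0
        elif actuator == "muscles":
            gains = {"P": (1.0, 0.0, 0.0), "PID": (1.0, 0.3, 0.3)}
            clamp = 1.0
        else:
            raise DomainError(f"no presets for actuator {actuator!r}")
        Kp, Ki, Kd = gains[mode]
        return cls(mode=mode, Kp=Kp, Ki=Ki, Kd=Kd, integral_clamp=clamp)


class DelayBuffer:
    """Ring of samples on a fixed-dt grid supporting pure-delay reads."""

    def __init__(self, dt: float, initial: float = 0.0):
        self.dt = dt
        self.samples = [initial]

    def append(self, value: float) -> None:
        self.samples.append(value)

    def read(self, t: float, delay: float) -> float:
        return delayed_signal(self.samples, t, self.dt, delay)


def delayed_signal(buffer, t: float, dt: float, delay: float) -> float:
    """Value of a sampled signal at time t - delay.

    ``buffer[k]`` is the sample at time k*dt.  Times before the first sample
    return the initial value (the signal is held at its t = 0 state during
    the dead time).  A delay that is not a multiple of dt is rounded to the
    nearest sample with a warning.
    """
    ratio = delay / dt
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"delay {delay} is not a multiple of dt {dt}; using nearest sample",
            stacklevel=2)
    idx = int(round(t / dt)) - int(round(ratio))
    idx = max(0, min(idx, len(buffer) - 1))
    return buffer[idx]


def perturbation_angle(t: float, spec: PerturbationSpec | None) -> tuple[float, float]:
    """Foot angle alpha(t) and rate, in radians (closed form)."""
    if spec is None:
        return 0.0, 0.0
    amp = spec.amplitude_deg * _DEG
    if spec.kind == "ramp":
        rate = spec.rate_dps * _DEG
        t_sat = amp / rate if rate > 0 else 0.0
        if t < t_sat:
            return rate * t, rate
        return amp, 0.0
    w = 2.0 * math.pi * spec.freq_hz
    return amp * math.sin(w * t), amp * w * math.cos(w * t)


def gravity_torque(beta: float, p: PendulumParams) -> float:
    """Destabilising gravity torque m g h_COG sin(beta) [N m] about the hinge."""
    return p.m * p.g * p.h_COG * math.sin(beta)


def _pid_output(cfg: ControllerConfig, e: float, e_dot: float, I: float) -> float:
    if cfg.mode == "none":
        return 0.0
    if cfg.mode == "P":
        return cfg.Kp * e
    i_term = cfg.Ki * I
    i_term = max(-cfg.integral_clamp, min(cfg.integral_clamp, i_term))
    return cfg.Kp * e + i_term + cfg.Kd * e_dot


def _muscle_kinematics(p: PendulumParams, l_ref: float, beta: float,
                       alpha: float, beta_dot: float, alpha_dot: float):
    rel = beta - alpha
    rel_dot = beta_dot - alpha_dot
    lA = l_ref + p.r_m * rel       # stretches as beta grows
    lB = l_ref - p.r_m * rel
    vA = p.r_m * rel_dot
    vB = -p.r_m * rel_dot
    return lA, lB, vA, vB


def _muscle_force(l_CE: float, q: float, l_MTU: float, v_MTU: float,
                  mp: MTUParams) -> tuple[float, float]:
    """(transmitted force, dl_CE/dt) for one MTU."""
    x = _contraction_rate(l_CE, q, l_MTU, v_MTU, mp)
    F = mtu_mod.ce_force(l_CE, x, q, mp) + mtu_mod.pee_force(l_CE, mp)
    return F, x


def actuator_torque(p: PendulumParams, cfg: ControllerConfig, pid: float,
                    beta: float, beta_dot: float, alpha: float,
                    alpha_dot: float, l_ref: float | None = None,
                    l_CE_pair: tuple[float, float] | None = None,
                    q_pair: tuple[float, float] | None = None) -> float:
    """Instantaneous hinge torque [N m] for the configured actuator.

    ``pid`` is the controller output computed from the *delayed* error.
    Torque mode commands ``-pid`` directly.  Muscle mode maps the joint
    angle to antagonistic MTU path lengths ``l_ref +/- r_m (beta - alpha)``,
    shifts the stimulations to ``clamp(q0 +/- pid, 0, 1)`` and returns
    ``r_m (F_flexor - F_extensor)``; the caller supplies the muscle states
    (CE lengths and, with activation dynamics, activations).
    """
    if p.actuator == "none":
        return 0.0
    if p.actuator == "torque":
        return -pid
    if l_ref is None or l_CE_pair is None:
        raise DomainError("muscle mode needs l_ref and the CE lengths")
    uA = min(max(p.q0 + pid, 0.0), 1.0)
    uB = min(max(p.q0 - pid, 0.0), 1.0)
    qA, qB = q_pair if q_pair is not None else (uA, uB)
    lA, lB, vA, vB = _muscle_kinematics(p, l_ref, beta, alpha,
                                        beta_dot, alpha_dot)
    FA, _ = _muscle_force(l_CE_pair[0], qA, lA, vA, p.mtu)
    FB, _ = _muscle_force(l_CE_pair[1], qB, lB, vB, p.mtu)
    return p.r_m * (FB - FA)


@dataclass
class SimulationResult:
    """Time series and summary of one pendulum run."""

    t: np.ndarray
    alpha: np.ndarray       # rad
    beta: np.ndarray        # rad
    tau: np.ndarray         # actuator torque [N m]
    u_a: np.ndarray | None  # stimulations (muscle runs only)
    u_b: np.ndarray | None
    q_a: np.ndarray | None
    q_b: np.ndarray | None
    toppled: bool
    topple_time: float | None
    config: dict

    def summary(self) -> dict:
        b = np.abs(self.beta) / _DEG
        return {
            "max_abs_beta_deg": float(b.max()),
            "rms_beta_deg": float(np.sqrt(np.mean((self.beta / _DEG) ** 2))),
            "toppled": bool(self.toppled),
            "topple_time_s": self.topple_time,
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.t, "alpha_deg": self.alpha / _DEG,
            "beta_deg": self.beta / _DEG, "tau_Nm": self.tau,
        })
        if self.u_a is not None:
            df["u_ext"] = self.u_a
            df["u_flex"] = self.u_b
            df["q_ext"] = self.q_a
            df["q_flex"] = self.q_b
        return df


# Dormand-Prince 5th-order stage coefficients (fixed step), local to the
# hand-rolled loop so the delay buffer stays aligned with the steps.
_DP_C = (0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0)
_DP_A = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (44 / 45, -56 / 15, 32 / 9),
    (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
    (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
)
_DP_B = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)


def simulate(p: PendulumParams,
             spec: PerturbationSpec | None = None,
             cfg: ControllerConfig = ControllerConfig(),
             duration: float = 10.0,
             dt: float = 0.001) -> SimulationResult:
    """Run the pendulum for ``duration`` seconds at fixed step ``dt``.

    Deterministic: identical inputs give bit-identical outputs.  Controller
    signals (delayed error, its rate, the stimulations / commanded torque)
    are sampled once per step and held across the Runge-Kutta stages, which
    matches a discrete controller with a zero-order hold.  The run stops
    early, flagged as toppled, once |beta| exceeds ``topple_deg``.
    """
    if duration <= 0 or dt <= 0:
        raise DomainError("duration and dt must be positive")
    n = int(round(duration / dt))
    mp = p.mtu
    muscles = p.actuator == "muscles"
    instant_act = mp.tau_act is None

    beta0 = p.beta0_deg * _DEG
    if muscles:
        l_ce0 = p.l_CE_init_rel * mp.l_CE_opt
        l_ref = mtu_mod.equilibrium_l_mtu(l_ce0, p.q0, mp)
        if instant_act:
            y = np.array([beta0, 0.0, l_ce0, l_ce0])
        else:
            y = np.array([beta0, 0.0, l_ce0, l_ce0, p.q0, p.q0])
    else:
        y = np.array([beta0, 0.0])

    t_arr = np.empty(n + 1)
    alpha_arr = np.empty(n + 1)
    beta_arr = np.empty(n + 1)
    tau_arr = np.empty(n + 1)
    if muscles:
        uA_arr = np.empty(n + 1)
        uB_arr = np.empty(n + 1)
        qA_arr = np.empty(n + 1)
        qB_arr = np.empty(n + 1)

    buffer = [beta0]
    I_err = 0.0
    topple_rad = p.topple_deg * _DEG
    toppled = False
    topple_time = None
    mgh = p.m * p.g * p.h_COG
    last = n

    def rhs(ti, yi, held):
        beta, beta_dot = yi[0], yi[1]
        alpha, alpha_dot = perturbation_angle(ti, spec)
        if muscles:
            uA, uB = held
            lA, lB, vA, vB = _muscle_kinematics(p, l_ref, beta, alpha,
                                                beta_dot, alpha_dot)
            lceA = min(max(yi[2], 0.3 * mp.l_CE_opt), lA - 1e-9)
            lceB = min(max(yi[3], 0.3 * mp.l_CE_opt), lB - 1e-9)
            if instant_act:
                qA, qB = uA, uB
            else:
                qA = min(max(yi[4], 0.0), 1.0)
                qB = min(max(yi[5], 0.0), 1.0)
            FA, xA = _muscle_force(lceA, qA, lA, vA, mp)
            FB, xB = _muscle_force(lceB, qB, lB, vB, mp)
            tau = p.r_m * (FB - FA)
            beta_ddot = (mgh * math.sin(beta) + tau) / p.J
            if instant_act:
                return np.array([beta_dot, beta_ddot, xA, xB]), tau
            return (np.array([beta_dot, beta_ddot, xA, xB,
                              (uA - qA) / mp.tau_act,
                              (uB - qB) / mp.tau_act]), tau)
        tau = held[0] if p.actuator == "torque" else 0.0
        beta_ddot = (mgh * math.sin(beta) + tau) / p.J
        return np.array([beta_dot, beta_ddot]), tau

    for i in range(n + 1):
        t = i * dt
        # --- discrete controller (zero-order hold over the step) ---
        e = delayed_signal(buffer, t, dt, cfg.delay)
        e_prev = delayed_signal(buffer, t - dt, dt, cfg.delay) if i else e
        e_dot = (e - e_prev) / dt if i else 0.0
        pid = _pid_output(cfg, e, e_dot, I_err)
        if muscles:
            held = (min(max(p.q0 + pid, 0.0), 1.0),
                    min(max(p.q0 - pid, 0.0), 1.0))
        elif p.actuator == "torque":
            held = (-pid,)
        else:
            held = (0.0,)

        dy0, tau_now = rhs(t, y, held)
        t_arr[i] = t
        alpha_arr[i], _ = perturbation_angle(t, spec)
        beta_arr[i] = y[0]
        tau_arr[i] = tau_now
        if muscles:
            uA_arr[i], uB_arr[i] = held
            if instant_act:
                qA_arr[i], qB_arr[i] = held
            else:
                qA_arr[i], qB_arr[i] = y[4], y[5]

        if abs(y[0]) > topple_rad:
            toppled = True
            topple_time = t
            last = i
            break
        if i == n:
            break

        # --- one fixed DP5 step ---
        k = [dy0]
        for s in range(1, 6):
            ys = y + dt * sum(a * kj for a, kj in zip(_DP_A[s], k))
            ks, _ = rhs(t + _DP_C[s] * dt, ys, held)
            k.append(ks)
        y = y + dt * sum(b * kj for b, kj in zip(_DP_B, k))
        if muscles and not instant_act:
            y[4] = min(max(y[4], 0.0), 1.0)
            y[5] = min(max(y[5], 0.0), 1.0)

        buffer.append(y[0])
        I_err += e * dt
        if cfg.Ki > 0 and math.isfinite(cfg.integral_clamp):
            lim = cfg.integral_clamp / cfg.Ki
            I_err = max(-lim, min(lim, I_err))

    sl = slice(0, last + 1)
    config = {
        "actuator": p.actuator, "controller": cfg.mode,
        "Kp": cfg.Kp, "Ki": cfg.Ki, "Kd": cfg.Kd, "delay_s": cfg.delay,
        "perturbation": None if spec is None else spec.kind,
        "dt": dt, "duration": duration,
        "beta0_deg": p.beta0_deg, "topple_deg": p.topple_deg,
    }
    if muscles:
        config.update({"r_m": p.r_m, "q0": p.q0,
                       "l_CE_init_rel": p.l_CE_init_rel, "l_ref_m": l_ref})
    return SimulationResult(
        t=t_arr[sl], alpha=alpha_arr[sl], beta=beta_arr[sl], tau=tau_arr[sl],
        u_a=uA_arr[sl] if muscles else None,
        u_b=uB_arr[sl] if muscles else None,
        q_a=qA_arr[sl] if muscles else None,
        q_b=qB_arr[sl] if muscles else None,
        toppled=toppled, topple_time=topple_time, config=config)


def passive_growth_rate(p: PendulumParams | None = None,
                        beta0_deg: float = 1e-4,
                        fit_window: tuple[float, float] = (1.0, 2.0),
                        dt: float = 0.001) -> float:
    """Measured exponential growth rate [1/s] of the passive pendulum.

    Simulates the unactuated pendulum from a tiny initial angle and fits the
    slope of log|beta| over ``fit_window``; the analytic value for the
    linearised system is sqrt(m g h_COG / J) (= sqrt(g / h_COG) when
    J = m h^2).
    """
    if p is None:
        p = PendulumParams(actuator="none")
    else:
        p = replace(p, actuator="none")
    p = replace(p, beta0_deg=beta0_deg, topple_deg=89.0)
    res = simulate(p, spec=None, cfg=ControllerConfig(), duration=fit_window[1] + 0.2,
                   dt=dt)
    mask = (res.t >= fit_window[0]) & (res.t <= fit_window[1])
    coeffs = np.polyfit(res.t[mask], np.log(np.abs(res.beta[mask])), 1)
    return float(coeffs[0])
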