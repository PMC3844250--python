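"""Virtual isometric and isotonic quick-release experiments.

The hardware protocol these routines replicate: the far CE end is clamped
(electromagnet), the active element is switched fully on (A_AE steps from 0
to 1) and the construct builds up force against the serial spring.  For an
*isometric* experiment the clamp stays on; the time ``t_isom`` at which the
internal shortening stops and the plateau force ``F_CE_max`` are reported.
For an *isotonic quick release* the clamp opens at ``t_QR`` (default 3 s) and
the CE then shortens against a constant external force; the operating point
``(F_CE, v_CE)`` is read off at ``t_eval`` (default 3.5 s).  Sweeping the
external force over a grid of load levels traces the force-velocity curve.

The electromagnet is modelled as an instantaneous boundary-condition switch;
the released load is by default an ideal (massless) constant-force boundary,
which is the faithful idealisation of the force-controlled motor that loads
the hardware rig.  An inertial point-load mode is available for studying the
ringing a real released mass exhibits (see ``ExternalForce``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ce_core
from .ce_core import CEParams, CEState, ExternalForce, FixedEnd
from .errors import DomainError, ProtocolError, UndefinedKappaError
from .fvcurve import FVCurve
from .integrators import dp5_step

__all__ = [
    "NoiseModel", "ProtocolConfig", "IsometricResult", "QuickReleaseResult",
    "run_isometric", "run_quick_release", "sweep_loads", "compute_kappa_v",
]

# isometric convergence: |node velocity| below this, sustained for 50 ms
_V_CONVERGED = 1e-5
_T_SUSTAIN = 0.05


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise for fixture generation (std devs)."""

    sigma_F: float = 0.0   # [N]
    sigma_v: float = 0.0   # [m/s]
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_F < 0 or self.sigma_v < 0:
            raise DomainError("noise standard deviations must be >= 0")
        if (self.sigma_F > 0 or self.sigma_v > 0) and self.seed is None:
            raise DomainError("a seed is required when noise is enabled")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing, load grid and repetition settings of the virtual protocol.

    t_QR        release time [s]
    t_eval      evaluation time [s]
    dt          fixed integration step [s]
    load_levels external forces [N]; None = 19 levels uniform in
                [0.02, 0.95] * F_CE_max (the measured isometric maximum)
    repetitions runs per load level (identical replicas unless noise is set)
    noise       optional measurement-noise model
    t_isom_max  time budget for isometric convergence [s]
    load_mode   "ideal" or "inertial" released boundary
    m_load      point-load mass for the inertial boundary [kg]
    """

    t_QR: float = 3.0
    t_eval: float = 3.5
    dt: float = 0.001
    load_levels: tuple[float, ...] | None = None
    repetitions: int = 10
    noise: NoiseModel | None = None
    t_isom_max: float = 10.0
    load_mode: str = "ideal"
    m_load: float = 0.1

    def __post_init__(self):
        if not (self.t_eval > self.t_QR > 0):
            raise DomainError("need t_eval > t_QR > 0")
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.repetitions < 1:
            raise DomainError("repetitions must be >= 1")
        if self.load_levels is not None and len(self.load_levels) > 0:
            lv = np.asarray(self.load_levels, float)
            if np.any(lv <= 0):
                raise DomainError("load levels must be positive")


@dataclass
class IsometricResult:
    trace: pd.DataFrame
    t_isom: float
    F_CE_max: float


@dataclass
class QuickReleaseResult:
    F_eval: float
    v_eval: float
    trace: pd.DataFrame
    F_ext: float
    no_shortening: bool = False


def _initial_state(p: CEParams) -> CEState:
    """Start with the serial spring exactly taut and the AE fully on."""
    return CEState(y1=p.l_CE_init - p.l_SE_slack, y2=p.l_CE_init, A_AE=1.0)


def _trace_frame(t, y1, y2, p: CEParams) -> pd.DataFrame:
    rows = []
    for ti, a, b in zip(t, y1, y2):
        f = ce_core.ce_forces(CEState(y1=a, y2=b, A_AE=1.0, t=ti), p)
        rows.append((ti, a, b, f.F_AE, f.F_PDE, f.F_SE, f.F_CE, f.slack))
    return pd.DataFrame(rows, columns=[
        "t", "y1", "y2", "F_AE", "F_PDE", "F_SE", "F_CE", "slack"])


def _hold_phase(p: CEParams, t_end: float, dt: float):
    """Integrate the clamped (isometric) phase; returns (t, y1) arrays."""
    s0 = _initial_state(p)
    n = int(round(t_end / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    y1 = np.empty(n + 1)
    y1[0] = s0.y1

    def rhs(ti, y):
        st = CEState(y1=float(y[0]), y2=s0.y2, A_AE=1.0, t=ti)
        return [ce_core.ce_rate(st, p, FixedEnd()).dy1_dt]

    y = np.array([s0.y1])
    for i in range(n):
        y = dp5_step(rhs, t[i], y, dt)
        y1[i + 1] = y[0]
    return t, y1, s0.y2


def run_isometric(p: CEParams, cfg: ProtocolConfig = ProtocolConfig()) -> IsometricResult:
    """Isometric contraction: clamp the far end, activate, wait for plateau.

    Convergence is declared when the internal shortening speed stays below
    1e-5 m/s for 50 ms; failing that within ``cfg.t_isom_max`` raises
    :class:`ProtocolError`.  With a rigid serial element nothing can move,
    so the plateau is reached instantly (t_isom = 0).
    """
    if p.rigid:
        trace = _trace_frame([0.0], [p.l_CE_init - p.l_SE_slack],
                             [p.l_CE_init], p)
        return IsometricResult(trace, 0.0, p.F_AE_max)

    t, y1, y2_0 = _hold_phase(p, cfg.t_isom_max, cfg.dt)
    F_SE = np.clip(p.k_SE * (y2_0 - y1 - p.l_SE_slack), 0.0, None)
    v1 = np.array([(p.F_AE_max - f) / ce_core.pde_damping_coefficient(f, p)
                   for f in F_SE])
    below = np.abs(v1) < _V_CONVERGED
    need = int(round(_T_SUSTAIN / cfg.dt))
    t_isom = None
    run = 0
    for i, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= need:
            t_isom = t[i - need + 1]
            break
    if t_isom is None:
        raise ProtocolError(
            f"isometric plateau not reached within {cfg.t_isom_max} s "
            f"(final |v1| = {abs(v1[-1]):.2e} m/s)")
    i_isom = int(round(t_isom / cfg.dt))
    trace = _trace_frame(t, y1, np.full_like(y1, y2_0), p)
    return IsometricResult(trace, float(t_isom), float(F_SE[i_isom]))


def run_quick_release(p: CEParams, F_ext: float,
                      cfg: ProtocolConfig = ProtocolConfig(),
                      _hold=None) -> QuickReleaseResult:
    """One isotonic quick-release contraction at external force F_ext.

    The end is clamped until ``t_QR`` and then loaded with constant
    ``F_ext``; the operating point is read at ``t_eval``.  ``_hold`` lets a
    sweep reuse the (load-independent) clamped phase.
    """
    if F_ext <= 0:
        raise DomainError("F_ext must be positive")

    dt = cfg.dt
    if _hold is None:
        _hold = _hold_phase(p, cfg.t_QR, dt) if not p.rigid else None

    if p.rigid:
        y1_qr = p.l_CE_init - p.l_SE_slack
        y2_qr = p.l_CE_init
        F_at_release = p.F_AE_max
    else:
        t_h, y1_h, y2_0 = _hold
        y1_qr, y2_qr = y1_h[-1], y2_0
        F_at_release = max(p.k_SE * (y2_qr - y1_qr - p.l_SE_slack), 0.0)

    if F_ext >= F_at_release:
        # load exceeds what the construct can lift: no shortening
        trace = _trace_frame([cfg.t_QR], [y1_qr], [y2_qr], p)
        return QuickReleaseResult(F_ext, 0.0, trace, F_ext, no_shortening=True)

    n_rel = int(round((cfg.t_eval - cfg.t_QR) / dt)) + 5  # margin for centred diff
    boundary = ExternalForce(F_ext, mode=cfg.load_mode, m_load=cfg.m_load)

    if cfg.load_mode == "ideal":
        # SE tension snaps to F_ext; y2 jumps so the spring carries F_ext
        y1 = np.empty(n_rel + 1)
        y1[0] = y1_qr

        def rhs(ti, y):
            st = CEState(y1=float(y[0]), y2=float(y[0]) + p.l_SE_slack,
                         A_AE=1.0, t=ti)
            return [ce_core.ce_rate(st, p, boundary).dy1_dt]

        y = np.array([y1_qr])
        for i in range(n_rel):
            y = dp5_step(rhs, cfg.t_QR + i * dt, y, dt)
            y1[i + 1] = y[0]
        stretch = 0.0 if p.rigid else F_ext / p.k_SE
        y2 = y1 + p.l_SE_slack + stretch
    else:
        def rhs(ti, y):
            st = CEState(y1=float(y[0]), y2=float(y[1]), A_AE=1.0, t=ti)
            r = ce_core.ce_rate(st, p, boundary)
            return [r.dy1_dt, y[2], r.dv2_dt]

        y = np.array([y1_qr, y2_qr, 0.0])
        y1 = np.empty(n_rel + 1)
        y2 = np.empty(n_rel + 1)
        y1[0], y2[0] = y1_qr, y2_qr
        for i in range(n_rel):
            y = dp5_step(rhs, cfg.t_QR + i * dt, y, dt)
            y1[i + 1], y2[i + 1] = y[0], y[1]

    t = cfg.t_QR + dt * np.arange(n_rel + 1)
    trace = _trace_frame(t, y1, y2, p)

    i_eval = int(round((cfg.t_eval - cfg.t_QR) / dt))
    F_eval = float(trace["F_CE"].iloc[i_eval])
    # centred difference of the total CE length, shortening positive
    v_eval = float(-(y2[i_eval + 1] - y2[i_eval - 1]) / (2 * dt))
    return QuickReleaseResult(F_eval, v_eval, trace, F_ext)


def sweep_loads(p: CEParams, cfg: ProtocolConfig = ProtocolConfig()) -> FVCurve:
    """Quick-release sweep over the load grid -> force-velocity curve.

    Repetitions are deterministic replicas of a single simulation per level
    unless a noise model is configured, in which case independent Gaussian
    measurement noise is drawn per repetition from the seeded generator.
    """
    if cfg.load_levels is not None:
        levels = np.asarray(cfg.load_levels, float)
    else:
        iso = run_isometric(p, cfg)
        levels = np.linspace(0.02, 0.95, 19) * iso.F_CE_max
    if levels.size < 2:
        raise DomainError("a sweep needs at least 2 load levels")

    hold = _hold_phase(p, cfg.t_QR, cfg.dt) if not p.rigid else None
    rng = (np.random.default_rng(cfg.noise.seed)
           if cfg.noise and (cfg.noise.sigma_F or cfg.noise.sigma_v) else None)

    rows = []
    for lv in levels:
        res = run_quick_release(p, float(lv), cfg, _hold=hold)
        for rep in range(cfg.repetitions):
            F, v = res.F_eval, res.v_eval
            if rng is not None:
                F += rng.normal(0.0, cfg.noise.sigma_F)
                v += rng.normal(0.0, cfg.noise.sigma_v)
            rows.append((float(lv), rep, F, v))
    df = pd.DataFrame(rows, columns=["load_N", "rep", "F_eval_N", "v_eval_mps"])
    return FVCurve(df, metadata={
        "protocol": "isotonic_quick_release",
        "t_QR": cfg.t_QR, "t_eval": cfg.t_eval, "dt": cfg.dt,
        "F_AE_max": p.F_AE_max, "R_PDE": p.R_PDE, "D_PDE": p.D_PDE,
        "k_SE": None if p.rigid else p.k_SE, "rigid": p.rigid,
        "noise": None if rng is None else
        {"sigma_F": cfg.noise.sigma_F, "sigma_v": cfg.noise.sigma_v,
         "seed": cfg.noise.seed},
    })


def compute_kappa_v(trace: pd.DataFrame, t_eval: float,
                    rigid: bool = False) -> float:
    """Serial-to-total velocity ratio kappa_v = v_SE / v_CE at t_eval.

    Both rates are centred finite differences of l_SE = y2 - y1 and
    l_CE = y2 on the trace.  A rigid serial element gives exactly 0; a
    vanishing total rate (e.g. the isometric phase) leaves the ratio
    undefined and raises :class:`UndefinedKappaError`.
    """
    if rigid:
        return 0.0
    t = trace["t"].to_numpy(float)
    i = int(np.argmin(np.abs(t - t_eval)))
    if i == 0 or i == t.size - 1:
        raise DomainError("t_eval is not interior to the trace")
    dt2 = t[i + 1] - t[i - 1]
    l_SE = trace["y2"].to_numpy(float) - trace["y1"].to_numpy(float)
    l_CE = trace["y2"].to_numpy(float)
    v_SE = -(l_SE[i + 1] - l_SE[i - 1]) / dt2
    v_CE = -(l_CE[i + 1] - l_CE[i - 1]) / dt2
    if abs(v_CE) < 1e-9:
        raise UndefinedKappaError(
            f"|v_CE| = {abs(v_CE):.2e} m/s at t = {t[i]:.3f} s; "
            "kappa_v is undefined at an isometric operating point")
    return float(v_SE / v_CE)
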