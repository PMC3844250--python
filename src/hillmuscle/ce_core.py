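"""Three-element contractile element (CE) as a continuous-time system.

The CE is a purely mechanical construct that produces a hyperbolic, Hill-like
force-velocity relation without any phenomenological fitting.  It consists of

* an **active element (AE)** — an ideal force source producing
  ``F_AE = A_AE * F_AE_max`` (activation ``A_AE`` in [0, 1]),
* a **parallel damping element (PDE)** — a damper across the AE whose
  coefficient rises linearly with the transmitted force,
* a **serial element (SE)** — a unilateral linear spring (a rope-and-spring
  in the hardware analogue) connecting the AE/PDE node to the load.

Geometry: the CE origin sits at y = 0, the AE/PDE node at ``y1`` and the far
end of the SE at ``y2``.  Hence ``l_AE = l_PDE = y1``, ``l_CE = y2`` and
``l_SE = y2 - y1``, which enforces the kinematic identity
``l_AE = l_PDE = l_CE - l_SE`` by construction.  The massless internal node
carries the force balance ``F_CE = F_SE = F_AE + F_PDE`` at all times.

Sign convention: public *contraction velocities are positive when
shortening*; geometric time derivatives ``dy/dt`` carry their natural sign
(shortening means dy1/dt < 0).

Because the AE is an ideal source and the PDE coefficient is linear in the
transmitted force, the steady operating points under constant load F obey

    v(F) = (F_AE_max - F) / ( D_eff * ((1 - R_PDE) F / F_AE_max + R_PDE) )

with ``D_eff = (1 - kappa_v) * D_PDE``, which is algebraically a Hill
hyperbola ``(F + a) v = b (P0 - F)`` with

    a = F_AE_max * R_PDE / (1 - R_PDE),
    b = F_AE_max / (D_eff * (1 - R_PDE)),      P0 = F_AE_max.

:func:`steady_state_fv` evaluates this closed form and serves as the analytic
oracle for the simulated quick-release experiments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SingularRateError
from .fvcurve import FVCurve

__all__ = [
    "CEParams", "CEState", "CEForces", "CERates",
    "FixedEnd", "ExternalForce",
    "pde_damping_coefficient", "ce_forces", "ce_rate", "steady_state_fv",
]


@dataclass(frozen=True)
class CEParams:
    """Design parameters of the contractile element.

    F_AE_max    maximum force of the active element [N]
    R_PDE       dimensionless damping-offset ratio in [0, 1]; the fraction of
                the maximum damping that remains at zero transmitted force
    D_PDE       maximum damping coefficient [N s/m]
    k_SE        serial spring stiffness [N/m]; ignored when ``rigid``
    l_SE_slack  rest length of the serial spring/rope [m]
    l_CE_init   initial total CE length y2(0) [m]
    rigid       model the SE as inextensible (the kappa_v = 0 idealisation)
    """

    F_AE_max: float
    R_PDE: float
    D_PDE: float
    k_SE: float = 2401.0
    l_SE_slack: float = 0.05
    l_CE_init: float = 0.30
    rigid: bool = False

    def __post_init__(self):
        if self.F_AE_max <= 0:
            raise DomainError("F_AE_max must be positive")
        if not 0.0 <= self.R_PDE <= 1.0:
            raise DomainError("R_PDE must lie in [0, 1]")
        if self.D_PDE <= 0:
            raise DomainError("D_PDE must be positive")
        if not self.rigid and self.k_SE <= 0:
            raise DomainError("k_SE must be positive (or set rigid=True)")
        if self.l_SE_slack < 0 or self.l_CE_init <= self.l_SE_slack:
            raise DomainError("need l_CE_init > l_SE_slack >= 0")


@dataclass
class CEState:
    """Instantaneous CE configuration: node positions, activation, time."""

    y1: float
    y2: float
    A_AE: float = 1.0
    t: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.A_AE <= 1.0:
            raise DomainError("activation A_AE must lie in [0, 1]")

    @property
    def l_CE(self) -> float:
        return self.y2

    @property
    def l_SE(self) -> float:
        return self.y2 - self.y1


@dataclass(frozen=True)
class CEForces:
    """Element forces [N] plus the force-balance residual and slack flag."""

    F_AE: float
    F_PDE: float
    F_SE: float
    F_CE: float
    residual: float
    slack: bool


@dataclass(frozen=True)
class FixedEnd:
    """Isometric boundary: the far CE end y2 is clamped (electromagnet on)."""


@dataclass(frozen=True)
class ExternalForce:
    """Constant external force applied to the far CE end after release.

    mode "ideal"     massless force-controlled boundary: the SE tension equals
                     F_ext instantly (the hardware's force-controlled motor).
    mode "inertial"  a point load m_load carries F_ext; exposes the
                     underdamped load/spring ringing of a real released mass.
    """

    F_ext: float
    mode: str = "ideal"
    m_load: float = 0.1

    def __post_init__(self):
        if self.F_ext < 0:
            raise DomainError("external force cannot be negative (rope)")
        if self.mode not in ("ideal", "inertial"):
            raise DomainError(f"unknown boundary mode {self.mode!r}")
        if self.mode == "inertial" and self.m_load <= 0:
            raise DomainError("m_load must be positive")


@dataclass(frozen=True)
class CERates:
    """Time derivatives of the CE coordinates (natural geometric signs)."""

    dy1_dt: float
    dy2_dt: float
    dv2_dt: float | None = None  # only for the inertial boundary

    @property
    def v_shortening(self) -> float:
        """AE/PDE shortening speed (positive = concentric)."""
        return -self.dy1_dt


def pde_damping_coefficient(F_SE: float, p: CEParams) -> float:
    """Damping coefficient of the PDE at transmitted force F_SE [N s/m].

    Linear in the transmitted force:
    ``d = D_PDE * ((1 - R_PDE) * F_SE / F_AE_max + R_PDE)``, spanning
    [R_PDE * D_PDE, D_PDE] as F_SE spans [0, F_AE_max].
    """
    if F_SE < 0:
        raise DomainError("F_SE must be >= 0 (the rope cannot push)")
    return p.D_PDE * ((1.0 - p.R_PDE) * F_SE / p.F_AE_max + p.R_PDE)


def _se_force(s: CEState, p: CEParams) -> tuple[float, bool]:
    """Serial spring force and slack flag (unilateral: tension only)."""
    stretch = s.y2 - s.y1 - p.l_SE_slack
    if stretch <= 0:
        return 0.0, True
    return p.k_SE * stretch, False


def _node_velocity(F_AE: float, F_SE: float, p: CEParams) -> float:
    """Shortening speed of the internal node from the force balance."""
    d = pde_damping_coefficient(F_SE, p)
    if d == 0.0:
        raise SingularRateError(
            "PDE coefficient is zero (R_PDE = 0 and F_SE = 0); the node "
            "velocity is undefined.  Set R_PDE > 0.")
    return (F_AE - F_SE) / d


def _rigid_se_force(F_AE: float, v1: float, p: CEParams) -> float:
    """SE force under a rigid SE, from the balance F_SE = F_AE - d(F_SE) v1.

    The damping law is linear in F_SE, so the balance stays linear:
    F_SE (1 + D (1-R) v1 / F_max) = F_AE - D R v1.  Clamped at >= 0.
    """
    denom = 1.0 + p.D_PDE * (1.0 - p.R_PDE) * v1 / p.F_AE_max
    F = (F_AE - p.D_PDE * p.R_PDE * v1) / denom
    return max(F, 0.0)


def ce_forces(s: CEState, p: CEParams, v_shortening: float | None = None) -> CEForces:
    """Element forces at a state.

    ``v_shortening`` is the AE/PDE node contraction speed (positive when
    shortening).  When omitted it is taken from the force balance itself, so
    the returned residual is zero by construction; pass an explicit value to
    audit the balance at an externally imposed node velocity.
    """
    F_AE = s.A_AE * p.F_AE_max
    if p.rigid:
        v1 = 0.0 if v_shortening is None else v_shortening
        F_SE = _rigid_se_force(F_AE, v1, p)
        slack = F_SE == 0.0
        F_PDE = F_SE - F_AE
        return CEForces(F_AE, F_PDE, F_SE, F_SE, 0.0, slack)
    F_SE, slack = _se_force(s, p)
    if v_shortening is None:
        v_shortening = _node_velocity(F_AE, F_SE, p)
    F_PDE = -pde_damping_coefficient(F_SE, p) * v_shortening
    residual = F_SE - (F_AE + F_PDE)
    return CEForces(F_AE, F_PDE, F_SE, F_SE, residual, slack)


def ce_rate(s: CEState, p: CEParams, boundary: FixedEnd | ExternalForce) -> CERates:
    """Time derivatives of (y1, y2) under the given boundary condition.

    The internal node is massless, so its velocity follows algebraically from
    the force balance: shortening speed ``v1 = (F_AE - F_SE) / d(F_SE)``.
    The far end is either clamped (isometric) or driven by the external load.
    """
    F_AE = s.A_AE * p.F_AE_max

    if isinstance(boundary, FixedEnd):
        if p.rigid:
            return CERates(0.0, 0.0)  # nothing can move
        F_SE, _ = _se_force(s, p)
        v1 = _node_velocity(F_AE, F_SE, p)
        return CERates(-v1, 0.0)

    if boundary.mode == "ideal":
        # massless force-controlled end: F_SE == F_ext at all times
        F_SE = boundary.F_ext
        v1 = _node_velocity(F_AE, F_SE, p)
        # constant SE tension => constant SE length => y2 tracks y1
        return CERates(-v1, -v1)

    # inertial load: y2 has its own dynamics, v2 must be tracked by caller
    if p.rigid:
        raise DomainError("inertial boundary with rigid SE is not supported")
    F_SE, _ = _se_force(s, p)
    v1 = _node_velocity(F_AE, F_SE, p)
    return CERates(-v1, math.nan, (boundary.F_ext - F_SE) / boundary.m_load)


def steady_state_fv(p: CEParams, kappa_v: float = 0.0,
                    F_levels=None) -> FVCurve:
    """Closed-form steady operating points F(v) of the CE construct.

    ``kappa_v`` is the fraction of the CE contraction velocity taken up by
    the serial element at the operating point (0 = rigid SE / constant SE
    tension).  The analytic oracle for the quick-release experiments.
    """
    if not 0.0 <= kappa_v < 1.0:
        raise DomainError("kappa_v must lie in [0, 1)")
    if F_levels is None:
        F_levels = np.linspace(0.02, 0.95, 19) * p.F_AE_max
    F = np.asarray(F_levels, dtype=float)
    if np.any(F < 0) or np.any(F > p.F_AE_max):
        raise DomainError("force levels must lie in [0, F_AE_max]")
    D_eff = (1.0 - kappa_v) * p.D_PDE
    v = (p.F_AE_max - F) / (D_eff * ((1.0 - p.R_PDE) * F / p.F_AE_max + p.R_PDE))
    return FVCurve.from_arrays(F, v, metadata={
        "source": "steady_state_fv", "kappa_v": kappa_v,
        "F_AE_max": p.F_AE_max, "R_PDE": p.R_PDE, "D_PDE": p.D_PDE,
    })
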