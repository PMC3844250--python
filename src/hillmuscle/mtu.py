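"""Macroscopic muscle-tendon-unit (MTU) model.

The actuator used for the inverted-pendulum study: a Hill-type contractile
element (CE) with a bell-shaped active force-length curve and a hyperbolic
force-velocity law (concentric branch per Hill, eccentric branch as the
standard continuous extension), a parallel elastic element (PEE) for passive
soft-tissue elasticity, and a serial elastic element (SEE) — a tendon-like
spring with a power-law toe region and linear continuation — with a small
force-dependent serial damping.

Default parameters describe a human tibialis anterior:
l_CE_opt = 0.1 m, F_max = 10 kN, bell width dW = 0.57, exponent nu_CE = 4,
normalised Hill constants A_rel0 = 0.25, B_rel0 = 2.25 1/s, SEE rest length
0.23 m, toe strain 0.1825, reference linear strain 0.073 at reference force
10 kN, serial damping D_SE = 0.3, R_SE = 0.01.

Sign conventions in this module are geometric: ``v_CE = dl_CE/dt`` and
``v_MTU = dl_MTU/dt`` are positive when *lengthening* (an eccentric CE has
v_CE > 0).  This differs from the shortening-positive convention of the
force-velocity curves in :mod:`hillmuscle.ce_core`; conversions happen at
the interfaces.

The CE length is the single mechanical state of the MTU.  Its rate follows
from the force equilibrium across the series junction,

    F_SEE(l_SEE) + d_SE * (v_MTU - v_CE) = F_CE(l_CE, v_CE, q) + F_PEE(l_CE),

which on each force-velocity branch is a quadratic in ``v_CE`` (the Hill
branch is a linear-fractional function of the rate and the serial damping
coefficient is linear in the transmitted force), solved in closed form by
:func:`contraction_rate`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, StateError

__all__ = [
    "MTUParams", "MTUState",
    "isometric_force_length", "see_force", "see_stiffness",
    "see_length_at_force", "pee_force", "ce_force",
    "contraction_rate", "mtu_force", "activation_rate", "equilibrium_l_mtu",
]


@dataclass(frozen=True)
class MTUParams:
    """MTU design parameters (defaults: human tibialis anterior).

    Force-length:  l_CE_opt [m], dW (bell half-width, normalised), nu_CE
    (bell exponent).  Force-velocity: A_rel0 (normalised Hill a), B_rel0
    [1/s] (normalised Hill b); eccentric branch with slope ratio
    ``ecc_slope_factor`` at v = 0 and force asymptote ``ecc_force_factor``
    times the isometric force.  SEE: rest length l_SEE0 [m], toe strain
    dU_SEE_nll, linear reference strain dU_SEE_l, reference force dF_SEE0
    [N]; the toe exponent dU_SEE_nll/dU_SEE_l follows from C1 continuity.
    Serial damping: D_SE (normalised magnitude), R_SE (offset ratio).  PEE:
    quadratic spring engaging at ``pee_slack_rel * l_CE_opt`` and reaching
    ``pee_force_factor * F_max`` at ``l_CE_opt * (1 + dW)``.  Activation:
    first-order time constant tau_act [s] (None = instantaneous).
    """

    l_CE_opt: float = 0.1
    F_max: float = 10000.0
    dW: float = 0.57
    nu_CE: float = 4.0
    A_rel0: float = 0.25
    B_rel0: float = 2.25
    l_SEE0: float = 0.23
    dU_SEE_nll: float = 0.1825
    dU_SEE_l: float = 0.073
    dF_SEE0: float = 10000.0
    D_SE: float = 0.3
    R_SE: float = 0.01
    # defaults not fixed by the tibialis parameter set (configurable)
    ecc_slope_factor: float = 2.0
    ecc_force_factor: float = 1.5
    pee_slack_rel: float = 0.95
    pee_force_factor: float = 2.0
    tau_act: float | None = 0.03

    def __post_init__(self):
        for name in ("l_CE_opt", "F_max", "dW", "A_rel0", "B_rel0", "l_SEE0",
                     "dU_SEE_nll", "dU_SEE_l", "dF_SEE0", "D_SE"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.nu_CE < 1:
            raise DomainError("nu_CE must be >= 1")
        if not 0.0 <= self.R_SE <= 1.0:
            raise DomainError("R_SE must lie in [0, 1]")
        if self.ecc_force_factor <= 1.0:
            raise DomainError("eccentric force asymptote must exceed 1")
        if self.tau_act is not None and self.tau_act <= 0:
            raise DomainError("tau_act must be positive (or None for instant)")

    # -- derived constants -------------------------------------------------
    @property
    def nu_SEE(self) -> float:
        """SEE toe exponent fixed by C1 continuity at the toe/linear junction."""
        return self.dU_SEE_nll / self.dU_SEE_l

    @property
    def k_SEE_linear(self) -> float:
        """SEE stiffness in the linear region [N/m]."""
        return self.dF_SEE0 / (self.dU_SEE_l * self.l_SEE0)

    @property
    def b_abs(self) -> float:
        """Hill b in absolute units [m/s]."""
        return self.B_rel0 * self.l_CE_opt

    @property
    def d_SE_max(self) -> float:
        """Maximum serial damping coefficient [N s/m]."""
        return self.D_SE * self.F_max * self.A_rel0 / (self.l_CE_opt * self.B_rel0)

    @property
    def pee_l0(self) -> float:
        return self.pee_slack_rel * self.l_CE_opt

    @property
    def pee_k2(self) -> float:
        """PEE quadratic coefficient [N/m^2]."""
        span = self.l_CE_opt * (1.0 + self.dW) - self.pee_l0
        return self.pee_force_factor * self.F_max / span ** 2


@dataclass
class MTUState:
    """Continuous MTU state: CE length, activation, imposed path kinematics."""

    l_CE: float
    q: float
    l_MTU: float
    v_MTU: float = 0.0  # dl_MTU/dt, lengthening positive

    def __post_init__(self):
        if self.l_CE <= 0:
            raise DomainError("l_CE must be positive")
        if not 0.0 <= self.q <= 1.0:
            raise DomainError("activation q must lie in [0, 1]")
        if self.l_MTU - self.l_CE < 0:
            raise DomainError("l_SEE = l_MTU - l_CE must be >= 0")

    @property
    def l_SEE(self) -> float:
        return self.l_MTU - self.l_CE


def isometric_force_length(l_CE: float, p: MTUParams) -> float:
    """Normalised active force-length factor exp(-|(l/l_opt - 1)/dW|^nu)."""
    if l_CE <= 0:
        raise DomainError("l_CE must be positive")
    x = (l_CE / p.l_CE_opt - 1.0) / p.dW
    return math.exp(-abs(x) ** p.nu_CE)


def see_force(l_SEE: float, p: MTUParams) -> float:
    """SEE (tendon) force [N]: zero below rest length, power-law toe up to
    strain dU_SEE_nll, linear beyond, C1-continuous at the junction."""
    eps = l_SEE / p.l_SEE0 - 1.0
    if eps <= 0.0:
        return 0.0
    if eps <= p.dU_SEE_nll:
        return p.dF_SEE0 * (eps / p.dU_SEE_nll) ** p.nu_SEE
    return p.dF_SEE0 + p.k_SEE_linear * p.l_SEE0 * (eps - p.dU_SEE_nll)


def see_stiffness(l_SEE: float, p: MTUParams) -> float:
    """dF_SEE/dl_SEE [N/m]."""
    eps = l_SEE / p.l_SEE0 - 1.0
    if eps <= 0.0:
        return 0.0
    if eps <= p.dU_SEE_nll:
        nu = p.nu_SEE
        return (nu * p.dF_SEE0 / (p.dU_SEE_nll * p.l_SEE0)
                * (eps / p.dU_SEE_nll) ** (nu - 1.0))
    return p.k_SEE_linear


def see_length_at_force(F: float, p: MTUParams) -> float:
    """Inverse of :func:`see_force` (F >= 0) -> l_SEE [m]."""
    if F < 0:
        raise DomainError("tendon force must be >= 0")
    if F == 0.0:
        return p.l_SEE0
    if F <= p.dF_SEE0:
        eps = p.dU_SEE_nll * (F / p.dF_SEE0) ** (1.0 / p.nu_SEE)
    else:
        eps = p.dU_SEE_nll + (F - p.dF_SEE0) / (p.k_SEE_linear * p.l_SEE0)
    return p.l_SEE0 * (1.0 + eps)


def pee_force(l_CE: float, p: MTUParams) -> float:
    """Parallel elastic force [N]: quadratic above the PEE slack length."""
    x = l_CE - p.pee_l0
    return p.pee_k2 * x * x if x > 0.0 else 0.0


def ce_force(l_CE: float, v_CE: float, q: float, p: MTUParams) -> float:
    """Active CE force [N] at geometric rate v_CE = dl_CE/dt.

    Concentric branch (v_CE <= 0): Hill hyperbola with a = A_rel0 * F_max and
    b = B_rel0 * l_CE_opt, scaled by the isometric force q * F_max * f_l.
    Eccentric branch (v_CE > 0): continuous hyperbolic extension with slope
    ratio ``ecc_slope_factor`` at v = 0 and asymptote ``ecc_force_factor``
    times isometric.  Clamped at zero beyond the unloaded velocity.
    """
    if not 0.0 <= q <= 1.0:
        raise DomainError("q must lie in [0, 1]")
    P0 = q * p.F_max * isometric_force_length(l_CE, p)
    aF = p.A_rel0 * p.F_max
    b = p.b_abs
    if v_CE <= 0.0:
        F = (b * P0 + aF * v_CE) / (b - v_CE)
        return max(F, 0.0)
    if P0 <= 0.0:
        return 0.0
    F_asym = p.ecc_force_factor * P0
    b_e = (F_asym - P0) * b / (p.ecc_slope_factor * (P0 + aF))
    return (P0 * b_e + F_asym * v_CE) / (b_e + v_CE)


def _balance_residual(x, G, k1, c2, N0, N1, Dd, sig, v):
    F = (N0 + N1 * x) / (Dd + sig * x)
    return G + (k1 + c2 * F) * (v - x) - F


def contraction_rate(state: MTUState, p: MTUParams) -> float:
    """CE length rate dl_CE/dt [m/s] from the series force equilibrium.

    Solves F_SEE + d_SE (v_MTU - v_CE) = F_CE(v_CE) + F_PEE for v_CE, with
    d_SE = d_SE_max ((1 - R_SE)(F_CE + F_PEE)/F_max + R_SE).  On each Hill
    branch the balance is a quadratic in v_CE; the physical root is selected
    by the sign of the residual at v_CE = 0 and verified to 1e-6 * F_max.
    """
    return _contraction_rate(state.l_CE, state.q, state.l_MTU, state.v_MTU, p)


def _contraction_rate(l_CE: float, q: float, l_MTU: float, v_MTU: float,
                      p: MTUParams) -> float:
    F_SEE = see_force(l_MTU - l_CE, p)
    F_PEE = pee_force(l_CE, p)
    P0 = q * p.F_max * isometric_force_length(l_CE, p)
    aF = p.A_rel0 * p.F_max
    b = p.b_abs

    D0 = p.d_SE_max
    c1 = D0 * p.R_SE
    c2 = D0 * (1.0 - p.R_SE) / p.F_max
    G = F_SEE - F_PEE
    k1 = c1 + c2 * F_PEE

    # no active force at all: the balance is linear in the rate
    if P0 <= 0.0 and k1 > 0.0:
        return v_MTU + G / k1

    # branch selection by the residual at v_CE = 0 (F_CE(0) = P0)
    r0 = G + (k1 + c2 * P0) * v_MTU - P0

    if r0 > 0.0 and P0 > 0.0:
        # eccentric: F = (P0 b_e + F_asym x) / (b_e + x), x > 0
        F_asym = p.ecc_force_factor * P0
        b_e = (F_asym - P0) * b / (p.ecc_slope_factor * (P0 + aF))
        N0, N1, Dd, sig = P0 * b_e, F_asym, b_e, 1.0
        lo, hi = 0.0, None
    else:
        # concentric: F = (b P0 + aF x) / (b - x), x <= 0
        N0, N1, Dd, sig = b * P0, aF, b, -1.0
        lo, hi = None, 0.0

    A2 = -k1 * sig - c2 * N1
    A1 = G * sig + k1 * (v_MTU * sig - Dd) + c2 * (N1 * v_MTU - N0) - N1
    A0 = G * Dd + k1 * v_MTU * Dd + c2 * N0 * v_MTU - N0

    roots = []
    if A2 == 0.0:
        if A1 != 0.0:
            roots = [-A0 / A1]
    else:
        disc = A1 * A1 - 4.0 * A2 * A0
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-A1 - sq) / (2.0 * A2), (-A1 + sq) / (2.0 * A2)]

    tol = 1e-6 * p.F_max
    best = None
    for x in roots:
        if lo is not None and x < lo - 1e-12:
            continue
        if hi is not None and x > hi + 1e-12:
            continue
        if Dd + sig * x <= 0.0:
            continue
        if (N0 + N1 * x) < -1e-9:  # force would be negative on this branch
            continue
        r = _balance_residual(x, G, k1, c2, N0, N1, Dd, sig, v_MTU)
        if abs(r) <= tol and (best is None or abs(r) < abs(best[1])):
            best = (x, r)
    if best is not None:
        return best[0]

    # concentric force clamps to zero beyond the unloaded velocity:
    # the balance degenerates to G + k1 (v_MTU - x) = 0
    if sig < 0 and k1 > 0.0:
        x = v_MTU + G / k1
        x_zero = -b * P0 / aF if aF > 0 else 0.0  # rate where F_CE hits 0
        if x <= x_zero + 1e-12:
            return x

    raise StateError(
        "no physical root of the contraction-rate balance",
        diagnostics={"l_CE": l_CE, "q": q, "l_MTU": l_MTU, "v_MTU": v_MTU,
                     "F_SEE": F_SEE, "F_PEE": F_PEE, "P0": P0,
                     "roots": roots, "r0": r0})


def mtu_force(state: MTUState, p: MTUParams) -> float:
    """Force transmitted by the MTU [N] (= F_CE + F_PEE at the solved rate)."""
    x = contraction_rate(state, p)
    return ce_force(state.l_CE, x, state.q, p) + pee_force(state.l_CE, p)


def activation_rate(q: float, u: float, p: MTUParams) -> float:
    """First-order activation dynamics dq/dt = (u - q)/tau_act.

    With ``tau_act=None`` activation is algebraic (q = u); callers handle
    that mode themselves and this function returns 0.
    """
    if not 0.0 <= u <= 1.0 or not 0.0 <= q <= 1.0:
        raise DomainError("u and q must lie in [0, 1]")
    if p.tau_act is None:
        return 0.0
    return (u - q) / p.tau_act


def equilibrium_l_mtu(l_CE: float, q: float, p: MTUParams) -> float:
    """MTU path length at which the state (l_CE, q) is a static equilibrium."""
    F = q * p.F_max * isometric_force_length(l_CE, p) + pee_force(l_CE, p)
    return l_CE + see_length_at_force(F, p)
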