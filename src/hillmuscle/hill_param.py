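"""Hill's force-velocity equation, hyperbola fitting, and design conversions.

Hill's relation for concentric contraction is ``(P + a) v = b (P0 - P)``:
``P`` the muscle force, ``v`` the shortening velocity, ``P0`` the maximum
isometric force and ``(a, b)`` the dynamic constants.  For the three-element
contractile element of :mod:`hillmuscle.ce_core` the same hyperbola follows
from two design parameters, the damping-offset ratio ``R_PDE`` and the
effective damping ``D_eff = (1 - kappa_v) * D_PDE``:

    a = F_max R_PDE / (1 - R_PDE)          (hyperbola matching)
    b = F_max / (D_eff (1 - R_PDE))        (isometric slope matching)

and inversely

    R_PDE = a / (a + F_max),    D_eff = (F_max + a) / b.

:func:`hill_to_design` / :func:`design_to_hill` implement this exact
algebraic pair, so a published (A, B, F_max) triple is all that is needed to
dimension a technical muscle of that type.  A packaged catalogue carries six
literature muscles (piglet, cat, rat, frog) with their published Hill
constants and derived design parameters.

Note: the catalogue's printed R_PDE column is reproduced by
``a / (a + F_max)`` only for the rat gastrocnemius row; the remaining printed
values do not follow from any inversion of the printed (A, B, F_max) triples
that we could identify.  :func:`load_catalog` therefore keeps the printed
values verbatim and exposes the closed-form inversion separately.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ce_core import CEParams
from .errors import CatalogError, DomainError, FitError
from .fvcurve import FVCurve

__all__ = [
    "HillConstants", "MuscleCatalogEntry", "HillFit",
    "hill_force", "hill_velocity", "fit_hyperbola",
    "hill_to_design", "design_to_hill",
    "load_catalog", "catalog_dataframe", "design_params_for", "read_fv_csv",
]

_CATALOG_SHA256 = "fa9e352e3e09a8cf97e5304e4cd46f08dc82fade5d61938fed2f8cfcdacde82f"


@dataclass(frozen=True)
class HillConstants:
    """Hill's dynamic constants: a [N], b [m/s], P0 [N] (all > 0)."""

    a: float
    b: float
    P0: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.P0 <= 0:
            raise DomainError("Hill constants a, b, P0 must all be positive")

    @property
    def v_max(self) -> float:
        """Unloaded shortening velocity b * P0 / a."""
        return self.b * self.P0 / self.a


@dataclass(frozen=True)
class MuscleCatalogEntry:
    """One literature muscle: published Hill constants and design parameters."""

    name: str
    A: float          # Hill a [N]
    B: float          # Hill b [m/s]
    F_max: float      # maximum isometric force [N]
    l_CE_opt: float   # optimal CE length [m]
    R_PDE: float      # printed damping-offset ratio (verbatim)
    D_eff: float      # printed (1 - kappa_v) D_PDE [N s/m]
    source: str

    @property
    def hill(self) -> HillConstants:
        return HillConstants(self.A, self.B, self.F_max)


@dataclass
class HillFit:
    """Result of a hyperbola fit: constants, R^2 on forces, residuals."""

    constants: HillConstants
    r_squared: float
    residuals: np.ndarray
    n_points: int
    P0_mode: str


def hill_force(h: HillConstants, v) -> np.ndarray | float:
    """Force P(v) on the concentric branch: ``P = (b P0 - a v) / (v + b)``.

    Clamped at zero beyond the unloaded velocity v_max (a warning is issued);
    negative velocities (eccentric branch) are outside this operation's
    domain — the eccentric extension lives in :mod:`hillmuscle.mtu`.
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise DomainError("hill_force is defined for v >= 0 (concentric)")
    P = (h.b * h.P0 - h.a * v_arr) / (v_arr + h.b)
    if np.any(P < 0):
        warnings.warn("velocity beyond v_max; force clamped at 0",
                      stacklevel=2)
        P = np.clip(P, 0.0, None)
    return float(P) if np.isscalar(v) else P


def hill_velocity(h: HillConstants, P) -> np.ndarray | float:
    """Shortening velocity v(P) = b (P0 - P) / (P + a); inverse of hill_force."""
    P_arr = np.asarray(P, dtype=float)
    if np.any(P_arr < 0) or np.any(P_arr > h.P0):
        raise DomainError("force must lie in [0, P0]")
    v = h.b * (h.P0 - P_arr) / (P_arr + h.a)
    return float(v) if np.isscalar(P) else v


def _extract_vf(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, FVCurve):
        return curve.velocities, curve.forces
    if isinstance(curve, pd.DataFrame):
        return (curve["v_eval_mps"].to_numpy(float),
                curve["F_eval_N"].to_numpy(float))
    v, F = curve
    return np.asarray(v, float), np.asarray(F, float)


def fit_hyperbola(curve, P0_mode: str = "free",
                  P0: float | None = None) -> HillFit:
    """Least-squares Hill-hyperbola fit of force as a function of velocity.

    R^2 is computed on force residuals because the quick-release protocol
    extracts forces at fixed evaluation times.  With ``P0_mode="fixed"`` the
    isometric force is held at the supplied ``P0`` (e.g. the value measured
    by the isometric experiment) and only (a, b) are fitted.

    Initialisation: a0 = 0.25 * P0, b0 = 0.25 * max observed velocity, with
    positivity bounds on all parameters.
    """
    v, F = _extract_vf(curve)
    if np.unique(v).size < (2 if P0_mode == "fixed" else 3):
        raise DomainError("need at least 3 distinct velocities (2 if P0 fixed)")
    if P0_mode not in ("free", "fixed"):
        raise DomainError("P0_mode must be 'free' or 'fixed'")
    if P0_mode == "fixed" and P0 is None:
        raise DomainError("P0_mode='fixed' requires an explicit P0")

    P0_guess = P0 if P0 is not None else float(np.max(F))
    a0, b0 = 0.25 * P0_guess, 0.25 * float(np.max(v))
    x0 = [a0, b0] if P0_mode == "fixed" else [a0, b0, P0_guess]
    try:
        if P0_mode == "fixed":
            def model(v, a, b):
                return (b * P0 - a * v) / (v + b)
            popt, _ = curve_fit(model, v, F, p0=x0,
                                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                                maxfev=20000)
            constants = HillConstants(popt[0], popt[1], P0)
        else:
            def model(v, a, b, p0):
                return (b * p0 - a * v) / (v + b)
            popt, _ = curve_fit(model, v, F, p0=x0,
                                bounds=([1e-12] * 3, [np.inf] * 3),
                                maxfev=20000)
            constants = HillConstants(*popt)
    except RuntimeError as exc:
        raise FitError(f"hyperbola fit did not converge: {exc}",
                       initial_guess=x0) from exc

    pred = (constants.b * constants.P0 - constants.a * v) / (v + constants.b)
    resid = F - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HillFit(constants, r2, resid, v.size, P0_mode)


def hill_to_design(A: float, B: float, F_max: float) -> tuple[float, float]:
    """Design parameters (R_PDE, D_eff) from Hill constants (A, B, F_max).

    Slope matching gives ``D_eff = (F_max + A) / B``; hyperbola matching
    gives ``R_PDE = A / (A + F_max)``.
    """
    if A <= 0 or B <= 0 or F_max <= 0:
        raise DomainError("A, B, F_max must be positive")
    return A / (A + F_max), (F_max + A) / B


def design_to_hill(R_PDE: float, D_eff: float, F_max: float) -> tuple[float, float]:
    """Hill constants (A, B) from design parameters; exact inverse of
    :func:`hill_to_design`."""
    if not 0.0 <= R_PDE < 1.0:
        raise DomainError("R_PDE must lie in [0, 1)")
    if D_eff <= 0 or F_max <= 0:
        raise DomainError("D_eff and F_max must be positive")
    A = F_max * R_PDE / (1.0 - R_PDE)
    B = F_max / (D_eff * (1.0 - R_PDE))
    return A, B


def _catalog_bytes() -> bytes:
    return (resources.files("hillmuscle") / "data" / "muscle_catalog.csv").read_bytes()


def catalog_dataframe() -> pd.DataFrame:
    """The packaged muscle catalogue as a DataFrame (integrity-checked)."""
    raw = _catalog_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CATALOG_SHA256:
        raise CatalogError(
            f"packaged catalogue checksum mismatch ({digest[:12]}...)")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw))
    if len(df) != 6:
        raise CatalogError(f"catalogue must have 6 rows, found {len(df)}")
    num = df[["A_N", "B_mps", "F_max_N", "l_CE_opt_m", "R_PDE", "D_eff_Nspm"]]
    if (num <= 0).any().any():
        raise CatalogError("catalogue contains non-positive parameters")
    # slope-matching consistency of the printed effective damping column
    recomputed = (df["F_max_N"] + df["A_N"]) / df["B_mps"]
    rel = np.abs(recomputed - df["D_eff_Nspm"]) / df["D_eff_Nspm"]
    if (rel > 0.02).any():
        raise CatalogError("printed D_eff deviates >2% from (F_max + A)/B")
    return df


def load_catalog() -> list[MuscleCatalogEntry]:
    """The six packaged literature muscles."""
    df = catalog_dataframe()
    return [
        MuscleCatalogEntry(r.name_, r.A_N, r.B_mps, r.F_max_N, r.l_CE_opt_m,
                           r.R_PDE, r.D_eff_Nspm, r.source)
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def design_params_for(entry: MuscleCatalogEntry, k_SE: float = 2401.0,
                      rigid: bool = False, l_SE_slack: float = 0.05,
                      l_CE_init: float = 0.30) -> CEParams:
    """CE design parameters for a catalogue muscle.

    Uses the closed-form inversion of the published Hill constants (not the
    catalogue's printed R_PDE column, which is inconsistent with it for five
    of the six rows) so that the resulting construct reproduces the
    published hyperbola exactly.
    """
    R, D_eff = hill_to_design(entry.A, entry.B, entry.F_max)
    return CEParams(F_AE_max=entry.F_max, R_PDE=R, D_PDE=D_eff, k_SE=k_SE,
                    rigid=rigid, l_SE_slack=l_SE_slack, l_CE_init=l_CE_init)


def read_fv_csv(path: str | Path) -> FVCurve:
    """Read a user force-velocity table (columns force_N, velocity_mps)."""
    return FVCurve.from_csv(path)
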