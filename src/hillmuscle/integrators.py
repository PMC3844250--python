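"""Fixed-step explicit Runge-Kutta integration.

All simulations in this package use the 5th-order Dormand-Prince scheme at a
fixed step (the classic "ODE5" configuration of fixed-step Simulink solvers):
the stage coefficients of DOPRI5(4) evaluated once per step with the 5th-order
weights and no step-size control.  Fixed stepping keeps delayed-feedback
buffers exactly aligned with the solution samples and makes runs bit-for-bit
reproducible, which adaptive scipy integrators do not guarantee.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

# Dormand-Prince 5(4) Butcher tableau (5th-order weights only).
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0])
_A = [
    np.array([]),
    np.array([1 / 5]),
    np.array([3 / 40, 9 / 40]),
    np.array([44 / 45, -56 / 15, 32 / 9]),
    np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729]),
    np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656]),
]
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])


def dp5_step(f: Callable, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    """Advance ``y' = f(t, y)`` by one fixed Dormand-Prince step of size dt."""
    k = []
    for i in range(6):
        yi = y if i == 0 else y + dt * sum(a * kj for a, kj in zip(_A[i], k))
        k.append(np.asarray(f(t + _C[i] * dt, yi), dtype=float))
    return y + dt * sum(b * kj for b, kj in zip(_B, k))


def integrate_fixed(
    f: Callable,
    t0: float,
    y0: Sequence[float],
    dt: float,
    n_steps: int,
    callback: Callable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate with n_steps fixed DP5 steps.

    Returns (t, Y) where t has n_steps+1 samples and Y has matching rows.
    ``callback(i, t, y)`` runs after each step and may return True to stop
    early (arrays are truncated accordingly).
    """
    y = np.asarray(y0, dtype=float)
    t_out = np.empty(n_steps + 1)
    y_out = np.empty((n_steps + 1, y.size))
    t_out[0] = t0
    y_out[0] = y
    t = t0
    for i in range(n_steps):
        y = dp5_step(f, t, y, dt)
        t = t0 + (i + 1) * dt
        t_out[i + 1] = t
        y_out[i + 1] = y
        if callback is not None and callback(i + 1, t, y):
            return t_out[: i + 2], y_out[: i + 2]
    return t_out, y_out
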