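"""Force-velocity curve container.

An :class:`FVCurve` is the set of (force, velocity) operating points that the
isotonic quick-release protocol produces (one point per load level and
repetition), or that a user measured on hardware.  Velocities are speeds of
shortening (positive = concentric), forces are in newtons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: canonical column order for CSV round-trips
COLUMNS = ["load_N", "rep", "F_eval_N", "v_eval_mps"]


@dataclass
class FVCurve:
    """Operating points of a contraction, as a tidy table.

    ``points`` columns: load_N (commanded external force), rep (repetition
    index), F_eval_N, v_eval_mps (measured at the evaluation instant).
    ``metadata`` records the generating parameter set and protocol.
    """

    points: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"FVCurve table is missing columns {missing}")
        self.points = self.points[COLUMNS].reset_index(drop=True)

    @property
    def forces(self) -> np.ndarray:
        return self.points["F_eval_N"].to_numpy(float)

    @property
    def velocities(self) -> np.ndarray:
        return self.points["v_eval_mps"].to_numpy(float)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_levels(self) -> int:
        return self.points["load_N"].nunique()

    @classmethod
    def from_arrays(cls, forces, velocities, loads=None, reps=None,
                    metadata=None) -> "FVCurve":
        forces = np.asarray(forces, float)
        velocities = np.asarray(velocities, float)
        if loads is None:
            loads = forces
        if reps is None:
            reps = np.zeros(forces.size, int)
        df = pd.DataFrame({
            "load_N": np.asarray(loads, float),
            "rep": np.asarray(reps, int),
            "F_eval_N": forces,
            "v_eval_mps": velocities,
        })
        return cls(df, metadata or {})

    def to_csv(self, path: str | Path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FVCurve":
        df = pd.read_csv(path)
        # accept bare measurement tables (force_N, velocity_mps)
        if "force_N" in df.columns and "velocity_mps" in df.columns:
            return cls.from_arrays(df["force_N"], df["velocity_mps"],
                                   metadata={"source": str(path)})
        return cls(df, {"source": str(path)})
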