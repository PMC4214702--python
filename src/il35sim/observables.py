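"""Scalar summaries of trajectories: totals, scenario ratios, drug efficacy.

All comparisons between the two mouse scenarios and between dosing schedules
reduce to sphere-integrated field totals at matched times; "week 2" means
t = 14 days and "two months" t = 56 days in the week-aligned calendar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import FIELDS
from .radial_pde import RadialGrid, Trajectory

__all__ = [
    "total_over_sphere",
    "scenario_ratio",
    "efficacy_ratio",
    "peak_location",
    "totals_table",
]


def total_over_sphere(field: np.ndarray, grid: RadialGrid) -> float:
    """Sphere integral of a radial field: sum of cell values times shell volumes."""
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n,):
        raise ValueError("field size does not match grid")
    return float(np.dot(grid.volumes, field))


def _total_at(traj: Trajectory, field: str, t: float) -> float:
    state = traj.state_at(t)
    return total_over_sphere(state.get(field), traj.grid)


def scenario_ratio(
    traj_a: Trajectory, traj_b: Trajectory, field: str, t: float
) -> float:
    """Ratio of sphere-integrated totals of ``field`` at time ``t`` (A over B)."""
    num = _total_at(traj_a, field, t)
    den = _total_at(traj_b, field, t)
    if den == 0.0:
        raise ZeroDivisionError(f"total of {field!r} vanishes in the denominator run")
    return num / den


def efficacy_ratio(traj_drug: Trajectory, traj_none: Trajectory, t: float) -> float:
    """Treated over untreated tumor burden at time ``t``; < 1 means benefit."""
    return scenario_ratio(traj_drug, traj_none, "c", t)


def peak_location(field: np.ndarray, grid: RadialGrid) -> float:
    """Radius of the maximal field value; ties resolve to the outermost cell."""
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n,):
        raise ValueError("field size does not match grid")
    rev = field[::-1]
    idx = grid.n - 1 - int(np.argmax(rev))
    return float(grid.centers[idx])


def totals_table(traj: Trajectory) -> pd.DataFrame:
    """Sphere-integrated totals of every field at every output time."""
    rows = {
        name: [total_over_sphere(traj.states[k, i], traj.grid)
               for k in range(len(traj.times))]
        for i, name in enumerate(FIELDS)
    }
    return pd.DataFrame({"time": traj.times, **rows})
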