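"""High-level drivers: one call from scenario name to trajectory."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .initial_conditions import quasi_steady_initials, tumor_initial_profile
from .parameters import ModelParameters, ScalingSystem, load_scenario, nondimensionalize
from .radial_pde import FieldState, Trajectory, build_grid, integrate
from .treatment import TreatmentProtocol

__all__ = ["default_initial_state", "simulate_scenario"]

#: default radial resolution of reference runs
DEFAULT_N_CELLS = 100


def default_initial_state(p_nd: ModelParameters, grid) -> FieldState:
    """Tumor seed plus quasi-steady companion fields on the given grid."""
    c0 = tumor_initial_profile(grid, p_nd)
    return quasi_steady_initials(grid, c0, p_nd)


def simulate_scenario(
    scenario: str = "J558-IL-35",
    t_out: Sequence[float] | None = None,
    n_cells: int = DEFAULT_N_CELLS,
    protocol: TreatmentProtocol | None = None,
    overrides: Mapping[str, float] | None = None,
    scaling: ScalingSystem | None = None,
    params: ModelParameters | None = None,
    **solver_options,
) -> Trajectory:
    """Run one scenario end to end (nondimensional integration).

    ``overrides`` are dimensional parameter replacements applied before
    scaling; pass ``params`` to supply a ready-made dimensional set instead.
    Times are in days (the time scale is one day).  Default outputs are
    weekly through ``t_final``.
    """
    scaling = scaling or ScalingSystem()
    if params is None:
        params = load_scenario(scenario, overrides=overrides)
    elif overrides:
        params = params.replace(**{k: float(v) for k, v in overrides.items()})
    p_nd = nondimensionalize(params, scaling)
    if t_out is None:
        t_out = np.arange(7.0, p_nd.t_final * scaling.time + 0.5, 7.0)
    grid = build_grid(p_nd.R_domain, n_cells)
    ic = default_initial_state(p_nd, grid)
    return integrate(ic, p_nd, grid, t_out, protocol=protocol, **solver_options)
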