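"""Initial fields: a centered tumor seed plus quasi-steady companions.

The tumor starts concentrated near the center as a Gaussian in r.  Fast
cytokines and the cell populations it recruits start on the quasi-steady
profiles their own balances imply given that seed (uniform production/decay
ratios), activated CD8+ T cells start at zero, and endothelial cells and
oxygen rise from depressed central values toward their healthy-tissue levels
at the rim, through which they are supplied.
"""

from __future__ import annotations

import numpy as np

from .kinetics import vegf_hypoxia_factor
from .parameters import FIELDS, ModelParameters
from .radial_pde import FieldState, RadialGrid

__all__ = ["tumor_initial_profile", "quasi_steady_initials"]

_IDX = {name: i for i, name in enumerate(FIELDS)}


def tumor_initial_profile(grid: RadialGrid, p: ModelParameters) -> np.ndarray:
    """Gaussian tumor seed ``c_init_amp * exp(-(r / r_init_width)^2)``.

    Nonnegative, maximal at the center, strictly decreasing in r.
    """
    if p.c_init_amp <= 0 or p.r_init_width <= 0:
        raise ValueError("initial amplitude and width must be positive")
    return p.c_init_amp * np.exp(-((grid.centers / p.r_init_width) ** 2))


def quasi_steady_initials(
    grid: RadialGrid, c0: np.ndarray, p: ModelParameters
) -> FieldState:
    """Build the full ten-field initial state from a tumor seed profile.

    * M-CSF: ``q0 = (s_q / d_q) c0`` — the production/decay steady state of
      its own balance, so the q0/c0 ratio is uniform.
    * MDSC: centered Gaussian of width ``m_init_width`` whose amplitude is
      the steady MDSC balance (source + M-CSF polarization at the center
      M-CSF level, divided by the death rate); negligible near the rim.
    * CD8+ T: identically zero (no activated cells before recruitment).
    * Treg: fraction ``init_treg_frac`` of the local tumor + MDSC density
      (activation is triggered by both populations).
    * TGF-beta, IL-35, VEGF: quasi-steady production/decay given the cell
      profiles above.
    * EC and oxygen: quadratic profiles rising from depressed central
      fractions to exactly ``e_normal`` and ``w_0`` at r = R.
    """
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (grid.n,):
        raise ValueError("tumor seed does not match grid")
    if np.any(c0 < 0):
        raise ValueError("tumor seed must be nonnegative")

    vals = np.zeros((len(FIELDS), grid.n))
    r = grid.centers
    vals[_IDX["c"]] = c0

    q0 = (p.s_q / p.d_q) * c0
    vals[_IDX["q"]] = q0

    q_center = q0[0]
    m_amp = (p.s_M + p.lambda_MQ * p.M_0 * q_center / (p.K_q + q_center)) / p.d_M
    M0 = m_amp * np.exp(-((r / p.m_init_width) ** 2))
    vals[_IDX["M"]] = M0

    vals[_IDX["T"]] = 0.0

    R0 = p.init_treg_frac * (c0 + M0)
    vals[_IDX["R_treg"]] = R0

    beta0 = (p.lambda_beta_c * c0 + p.lambda_beta_R * R0) / p.d_beta
    vals[_IDX["beta"]] = beta0

    rho0 = (
        p.lambda_rho_c * c0 + p.lambda_rho_R * R0 + p.lambda_rho_M * M0
    ) / p.d_rho
    vals[_IDX["rho"]] = rho0

    x = (r / grid.R) ** 2
    e0 = p.e_normal * (p.e_init_frac + (1.0 - p.e_init_frac) * x)
    w0 = p.w_0 * (p.w_init_frac + (1.0 - p.w_init_frac) * x)
    vals[_IDX["e"]] = e0
    vals[_IDX["w"]] = w0

    G = vegf_hypoxia_factor(w0, p)
    h0 = G * (
        p.lambda_hc * c0 * (p.eps_c + rho0 / (p.K_rho_h + rho0))
        + p.lambda_hM * M0 * (p.eps_M + q0 / (p.K_q_h + q0))
    ) / p.d_h
    vals[_IDX["h"]] = h0

    return FieldState(values=vals, t=0.0)
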