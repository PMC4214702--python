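"""Grid-free reaction terms of the ten-field tumor–immune model.

Everything here is a pure function of a local state and a (dimensionless)
parameter set, so each nonlinear switch and source term is unit-testable in
isolation.  Spatial transport (diffusion, chemotaxis, boundary exchange)
lives in :mod:`il35sim.radial_pde`.

The local balances, per field (nondimensional units):

.. code-block:: text

    dc/dt    = lambda_c c (1 - c/c_max) f_p(w) - d_n c f_n(w) - d_c c - eta c T
    dq/dt    = s_q c - d_q q
    dM/dt    = s_M + lambda_M_rho rho/(K_rho + rho)
               + lambda_MQ M_0 q/(K_q + q) - d_M M
    drho/dt  = lambda_rho_c c + lambda_rho_R R + lambda_rho_M M
               - d_rho rho - mu_A rho A
    dR/dt    = lambda_RM M/(K_M + M) + lambda_R_beta beta/(K_beta + beta) - d_R R
    dbeta/dt = lambda_beta_c c + lambda_beta_R R - d_beta beta
    dT/dt    = lambda_T12 S12(M) / (1 + k_10M M / K_T1) - d_T T
    dh/dt    = G(w) [lambda_hc c (eps_c + rho/(K_rho_h + rho))
                     + lambda_hM M (eps_M + q/(K_q_h + q))] - d_h h
    de/dt    = lambda_e e (1 - e/e_max) H(h)
    dw/dt    = lambda_w e (w_0 - w) - (k_wT T + k_wM M + k_wR R + k_wc c) w

with ``f_p``/``f_n`` the piecewise-linear oxygen switches, ``G`` the hypoxic
VEGF factor peaking at ``w_star``, ``S12(M) = k_12M M / (K_T2 + k_12M M)``
the IL-12-mediated activation saturation, and ``H`` the thresholded EC
proliferation switch.  The anti-IL-35 drug ``A`` enters only the IL-35
equation, as the sink ``-mu_A rho A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import FIELDS, ModelParameters

__all__ = [
    "PointState",
    "proliferation_oxygen_switch",
    "necrosis_oxygen_switch",
    "vegf_hypoxia_factor",
    "ec_proliferation_switch",
    "il10_suppression",
    "reaction_rhs",
]

_IDX = {name: i for i, name in enumerate(FIELDS)}


@dataclass(frozen=True)
class PointState:
    """One nonnegative scalar per field, in nondimensional units."""

    c: float
    q: float
    M: float
    rho: float
    R_treg: float
    beta: float
    T: float
    h: float
    e: float
    w: float

    def as_array(self) -> np.ndarray:
        arr = np.array([getattr(self, name) for name in FIELDS], dtype=float)
        _check_state(arr)
        return arr


def _check_state(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    if np.any(x < 0):
        raise ValueError("state contains negative entries")


def _ramp(w, lo, hi, smooth: float = 0.0):
    """Piecewise-linear ramp from 0 at ``lo`` to 1 at ``hi``.

    ``smooth > 0`` replaces the corners by a C^1 cubic smoothstep of the same
    endpoints (width is absorbed into the ramp itself); default off preserves
    the piecewise form.
    """
    x = np.clip((np.asarray(w, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    if smooth > 0.0:
        x = x * x * (3.0 - 2.0 * x)
    return x


def proliferation_oxygen_switch(w, p: ModelParameters, smooth: float = 0.0):
    """Oxygen dependence of tumor proliferation, in [0, 1].

    Zero throughout the necrotic and extremely hypoxic ranges (w < w_hyp),
    rising linearly across the intermediate-hypoxic interval, and 1 at and
    above the normal oxygen level, where proliferation attains lambda_c.
    """
    if np.any(np.asarray(w) < 0):
        raise ValueError("oxygen level must be nonnegative")
    return _ramp(w, p.w_hyp, p.w_normal, smooth)


def necrosis_oxygen_switch(w, p: ModelParameters, smooth: float = 0.0):
    """Oxygen dependence of tumor necrosis, in [0, 1].

    Maximal (1) below w_nec, decaying linearly across the extremely hypoxic
    interval, zero from w_hyp upward (hence at the normal level).
    """
    if np.any(np.asarray(w) < 0):
        raise ValueError("oxygen level must be nonnegative")
    return 1.0 - _ramp(w, p.w_nec, p.w_hyp, smooth)


def vegf_hypoxia_factor(w, p: ModelParameters):
    """Hypoxic enhancement G(w) of VEGF secretion, maximal at ``w_star``.

    ``G(w) = (w / w_star) exp(1 - w / w_star)`` vanishes at w = 0 (dead
    tissue secretes nothing), peaks at exactly w = w_star (mild hypoxia), and
    decays toward well-oxygenated tissue, so G(w_normal) < G(w_star) = 1.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("oxygen level must be nonnegative")
    x = w / p.w_star
    return x * np.exp(1.0 - x)


def ec_proliferation_switch(h, p: ModelParameters):
    """Thresholded, saturating VEGF drive of EC proliferation.

    Zero for h <= h_star; for h above the threshold the excess saturates as
    ``(h - h_star) / (K_h + (h - h_star))``, bounded by 1.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("VEGF concentration must be nonnegative")
    excess = np.maximum(h - p.h_star, 0.0)
    return excess / (p.K_h + excess)


def il10_suppression(M, p: ModelParameters):
    """MDSC-derived IL-10 suppression of CD8+ T activation: 1/(1 + k_10M M/K_T1).

    Implemented as a named helper because the reciprocal form is the easiest
    term in the model to mis-transcribe.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("MDSC density must be nonnegative")
    return 1.0 / (1.0 + p.k_10M * M / p.K_T1)


def reaction_rhs(
    state: np.ndarray | PointState,
    p: ModelParameters,
    A: float | np.ndarray = 0.0,
    smooth: float = 0.0,
) -> np.ndarray:
    """All non-transport rates, one row per field.

    Parameters
    ----------
    state:
        A :class:`PointState` or array of shape ``(10,)`` or ``(10, n)``,
        nondimensional and nonnegative.
    p:
        Dimensionless parameter set.
    A:
        Local anti-IL-35 drug level (scalar or length-``n``); enters only the
        IL-35 balance as the sink ``-mu_A rho A``.

    Returns
    -------
    ndarray of the same shape as the state, ordered as
    ``(c, q, M, rho, R_treg, beta, T, h, e, w)``.
    """
    if isinstance(state, PointState):
        x = state.as_array()
    else:
        x = np.asarray(state, dtype=float)
        _check_state(x)
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or not np.all(np.isfinite(A)):
        raise ValueError("drug level must be nonnegative and finite")

    c, q, M, rho, R, beta, T, h, e, w = x

    f_p = proliferation_oxygen_switch(w, p, smooth)
    f_n = necrosis_oxygen_switch(w, p, smooth)
    G = vegf_hypoxia_factor(w, p)
    H = ec_proliferation_switch(h, p)

    out = np.empty_like(x)
    out[_IDX["c"]] = (
        p.lambda_c * c * (1.0 - c / p.c_max) * f_p
        - p.d_n * c * f_n
        - p.d_c * c
        - p.eta * c * T
    )
    out[_IDX["q"]] = p.s_q * c - p.d_q * q
    out[_IDX["M"]] = (
        p.s_M
        + p.lambda_M_rho * rho / (p.K_rho + rho)
        + p.lambda_MQ * p.M_0 * q / (p.K_q + q)
        - p.d_M * M
    )
    out[_IDX["rho"]] = (
        p.lambda_rho_c * c
        + p.lambda_rho_R * R
        + p.lambda_rho_M * M
        - p.d_rho * rho
        - p.mu_A * rho * A
    )
    out[_IDX["R_treg"]] = (
        p.lambda_RM * M / (p.K_M + M)
        + p.lambda_R_beta * beta / (p.K_beta + beta)
        - p.d_R * R
    )
    out[_IDX["beta"]] = p.lambda_beta_c * c + p.lambda_beta_R * R - p.d_beta * beta
    il12 = p.k_12M * M
    out[_IDX["T"]] = (
        p.lambda_T12 * il12 / (p.K_T2 + il12) * il10_suppression(M, p) - p.d_T * T
    )
    out[_IDX["h"]] = G * (
        p.lambda_hc * c * (p.eps_c + rho / (p.K_rho_h + rho))
        + p.lambda_hM * M * (p.eps_M + q / (p.K_q_h + q))
    ) - p.d_h * h
    out[_IDX["e"]] = p.lambda_e * e * (1.0 - e / p.e_max) * H
    out[_IDX["w"]] = (
        p.lambda_w * e * (p.w_0 - w)
        - (p.k_wT * T + p.k_wM * M + p.k_wR * R + p.k_wc * c) * w
    )
    return out
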