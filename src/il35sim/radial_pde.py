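"""Finite-volume discretization on the radius of a sphere and time integration.

The tumor occupies a fixed sphere of radius R.  Under radial symmetry every
field obeys a 1-D conservation law in r with the sphere measure 4*pi*r^2 dr.
Cells are the n equal-width shells between faces ``r_0 = 0 < ... < r_n = R``;
cell volumes are exact shell volumes, so the quadrature weights sum to the
sphere volume to machine precision and transported mass is conserved by
construction (fluxes telescope).

Transport terms:

* diffusion — central flux ``-D df/dr`` at faces;
* chemotaxis — advective flux ``chi * cells * d(attractant)/dr`` with
  first-order upwinding of the cell density (positivity over formal order);
* boundary — zero flux at r = 0 (the face has zero area) and at r = R for
  every field except endothelial cells and oxygen, which exchange with the
  healthy tissue through Robin fluxes ``gamma_e (e - e_normal)`` and
  ``gamma_w (w - w_0)`` (outward positive).

Time integration is method-of-lines with a stiff adaptive solver (LSODA by
default, banded Jacobian; BDF with a sparsity pattern as an option).  The
dose schedule is piecewise constant, so the integrator is restarted at every
switching instant rather than asked to step across a discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .kinetics import reaction_rhs
from .parameters import FIELDS, ModelParameters

__all__ = [
    "RadialGrid",
    "FieldState",
    "Trajectory",
    "SolverFailure",
    "build_grid",
    "diffusion_term",
    "chemotaxis_term",
    "boundary_fluxes",
    "integrate",
]

_IDX = {name: i for i, name in enumerate(FIELDS)}
#: fields that exchange with healthy tissue at r = R (all others are no-flux)
ROBIN_FIELDS = ("e", "w")
#: absolute undershoot beyond which a negative field value is an error
NEGATIVITY_TOL = 1e-10


class SolverFailure(RuntimeError):
    """Stiff integrator failed; message records the time reached."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform finite-volume grid on [0, R] with sphere-measure weights."""

    R: float
    n: int
    faces: np.ndarray  # (n+1,)
    centers: np.ndarray  # (n,)
    volumes: np.ndarray  # (n,) exact shell volumes; sum = 4/3 pi R^3
    face_areas: np.ndarray  # (n+1,) 4 pi r_f^2

    @property
    def dr(self) -> float:
        return self.R / self.n


def build_grid(R: float, n: int) -> RadialGrid:
    """Uniform radial grid with exact shell-volume quadrature weights."""
    if not R > 0:
        raise ValueError("domain radius must be positive")
    if n < 8:
        raise ValueError("need at least 8 cells")
    faces = np.linspace(0.0, R, n + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    volumes = 4.0 * np.pi / 3.0 * np.diff(faces**3)
    face_areas = 4.0 * np.pi * faces**2
    return RadialGrid(R=float(R), n=int(n), faces=faces, centers=centers,
                      volumes=volumes, face_areas=face_areas)


def _flux_divergence(face_flux: np.ndarray, grid: RadialGrid) -> np.ndarray:
    """Cell rates from outward-positive face fluxes: -(1/V) d(A*flux)."""
    aflux = grid.face_areas * face_flux
    return -(aflux[1:] - aflux[:-1]) / grid.volumes


def diffusion_term(
    f: np.ndarray,
    D: float,
    grid: RadialGrid,
    bc: tuple[float, float] | None = None,
) -> np.ndarray:
    """Discrete spherical Laplacian times D, conservative under no-flux.

    ``bc = (gamma, f_external)`` adds a Robin exchange flux
    ``gamma (f - f_external)`` (outward positive) at r = R; default no-flux.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (grid.n,):
        raise ValueError(f"field has shape {f.shape}, expected ({grid.n},)")
    flux = np.zeros(grid.n + 1)
    flux[1:-1] = -D * np.diff(f) / grid.dr  # r = 0 face has zero area anyway
    if bc is not None:
        gamma, f_ext = bc
        flux[-1] = gamma * (f[-1] - f_ext)
    return _flux_divergence(flux, grid)


def chemotaxis_term(
    cells: np.ndarray,
    attractant: np.ndarray,
    chi: float,
    grid: RadialGrid,
) -> np.ndarray:
    """Conservative divergence of the chemotactic flux chi * cells * grad(a).

    The drift velocity at each interior face is ``chi`` times the face-normal
    attractant gradient; the advected cell density is taken from the upwind
    cell.  Boundary faces carry no chemotactic flux, so the sphere integral
    of the returned rates vanishes identically.
    """
    cells = np.asarray(cells, dtype=float)
    attractant = np.asarray(attractant, dtype=float)
    if cells.shape != (grid.n,) or attractant.shape != (grid.n,):
        raise ValueError("cells/attractant size mismatch with grid")
    if chi < 0:
        raise ValueError("chemotactic sensitivity must be nonnegative")
    v = chi * np.diff(attractant) / grid.dr  # velocity at interior faces, +r
    upwind = np.where(v > 0.0, cells[:-1], cells[1:])
    flux = np.zeros(grid.n + 1)
    flux[1:-1] = v * upwind
    return _flux_divergence(flux, grid)


@dataclass
class FieldState:
    """The ten fields on a grid at one time (nondimensional by default)."""

    values: np.ndarray  # (10, n)
    t: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(FIELDS):
            raise ValueError(f"values must have shape (10, n), got {self.values.shape}")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field state contains non-finite values")
        if self.values.min() < -NEGATIVITY_TOL:
            raise ValueError(
                f"field state has negative entries below -{NEGATIVITY_TOL:g}"
            )

    def get(self, name: str) -> np.ndarray:
        return self.values[_IDX[name]]

    def copy(self) -> "FieldState":
        return FieldState(values=self.values.copy(), t=self.t)


def boundary_fluxes(state: FieldState, p: ModelParameters) -> np.ndarray:
    """Outward flux of each field through the outer face r = R.

    Zero for the no-flux species; Robin exchange toward the healthy-tissue
    levels for endothelial cells and oxygen.  A boundary EC density below
    ``e_normal`` therefore yields a negative outward flux, i.e. inward
    migration of EC from the surrounding tissue.
    """
    out = np.zeros(len(FIELDS))
    out[_IDX["e"]] = p.gamma_e * (state.get("e")[-1] - p.e_normal)
    out[_IDX["w"]] = p.gamma_w * (state.get("w")[-1] - p.w_0)
    return out


@dataclass
class Trajectory:
    """Method-of-lines solution at requested output times plus diagnostics."""

    times: np.ndarray  # (nt,)
    states: np.ndarray  # (nt, 10, n)
    grid: RadialGrid
    diagnostics: dict = field(default_factory=dict)

    def state_at(self, t: float) -> FieldState:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, rtol=1e-9, atol=1e-9):
            raise KeyError(f"time {t} not in trajectory (closest: {self.times[i]})")
        return FieldState(values=self.states[i].copy(), t=float(self.times[i]))

    def field_series(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name], :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, radius, field, value)."""
        nt, nf, n = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, nf * n),
                "radius": np.tile(self.grid.centers, nt * nf),
                "field": np.tile(np.repeat(list(FIELDS), n), nt),
                "value": self.states.ravel(),
            }
        )


def _band_sparsity(n: int, nf: int, half_band: int):
    m = nf * n
    pat = lil_matrix((m, m), dtype=np.int8)
    for i in range(m):
        lo, hi = max(0, i - half_band), min(m, i + half_band + 1)
        pat[i, lo:hi] = 1
    return pat.tocsr()


def integrate(
    ic: FieldState,
    p: ModelParameters,
    grid: RadialGrid,
    t_out: Sequence[float],
    protocol=None,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    include_reactions: bool = True,
    include_chemotaxis: bool = True,
    active_fields: Sequence[str] | None = None,
    smooth: float = 0.0,
) -> Trajectory:
    """Integrate the coupled ten-field system (nondimensional form).

    Parameters
    ----------
    ic:
        Initial :class:`FieldState` on ``grid``.
    p:
        Dimensionless parameter set (``p.dimensionless`` must be True).
    t_out:
        Strictly increasing output times; the first trajectory entry is the
        supplied initial condition.
    protocol:
        Optional :class:`il35sim.treatment.TreatmentProtocol`; the integrator
        is restarted at every dose-switching instant.
    include_reactions / include_chemotaxis / active_fields:
        Switch off term groups or freeze fields; used by conservation and
        single-field oracle tests and by steady-state checks.

    Returns
    -------
    :class:`Trajectory` with solver diagnostics (``nfev``, ``steps``,
    ``segments``, ``clipped`` undershoot count).
    """
    if not p.dimensionless:
        raise ValueError("integrate expects a nondimensionalized parameter set")
    if ic.values.shape[1] != grid.n:
        raise ValueError("initial condition does not match grid size")
    t_out = np.asarray(t_out, dtype=float)
    if t_out.ndim != 1 or len(t_out) == 0 or np.any(np.diff(t_out) <= 0):
        raise ValueError("t_out must be a nonempty strictly increasing sequence")
    if t_out[0] <= ic.t:
        raise ValueError("output times must lie strictly after the initial time")

    n, nf = grid.n, len(FIELDS)
    active = np.ones(nf, dtype=bool)
    if active_fields is not None:
        active[:] = False
        for name in active_fields:
            active[_IDX[name]] = True

    diffusivities = np.array(
        [getattr(p, d) for d in
         ("D_c", "D_q", "D_M", "D_rho", "D_R", "D_beta", "D_T", "D_h", "D_e", "D_w")]
    )
    robin = {
        _IDX["e"]: (p.gamma_e, p.e_normal),
        _IDX["w"]: (p.gamma_w, p.w_0),
    }
    if protocol is not None:
        from .treatment import drug_spatial_profile, protocol_breakpoints, protocol_level

        drug_shape = drug_spatial_profile(grid, 1.0, p)
        breakpoints = protocol_breakpoints(protocol)
    else:
        drug_shape = np.zeros(n)
        breakpoints = np.array([])

    def make_rhs(dose_level: float):
        A = dose_level * drug_shape

        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            X = y.reshape(n, nf).T  # (10, n)
            Xc = np.maximum(X, 0.0)
            rates = np.zeros((nf, n))
            for fi in range(nf):
                if not active[fi]:
                    continue
                rates[fi] = diffusion_term(X[fi], diffusivities[fi], grid,
                                           bc=robin.get(fi))
            if include_chemotaxis:
                if active[_IDX["M"]]:
                    rates[_IDX["M"]] += chemotaxis_term(
                        Xc[_IDX["M"]], X[_IDX["q"]], p.chi_M, grid)
                if active[_IDX["T"]]:
                    rates[_IDX["T"]] += chemotaxis_term(
                        Xc[_IDX["T"]], p.k_MCP * X[_IDX["M"]], p.chi_T, grid)
                if active[_IDX["e"]]:
                    rates[_IDX["e"]] += chemotaxis_term(
                        Xc[_IDX["e"]], X[_IDX["h"]], p.chi_e, grid)
            if include_reactions:
                rates[active] += reaction_rhs(Xc, p, A, smooth=smooth)[active]
            return rates.T.ravel()

        return rhs

    # segment boundaries: initial time, dose switches, final output time
    t0, t1 = float(ic.t), float(t_out[-1])
    seg_edges = np.unique(np.concatenate(
        [[t0, t1], breakpoints[(breakpoints > t0) & (breakpoints < t1)]]))

    options: dict = {}
    half_band = 2 * nf - 1
    if method == "LSODA":
        options.update(lband=half_band, uband=half_band)
    elif method == "BDF":
        options.update(jac_sparsity=_band_sparsity(n, nf, half_band))

    y = ic.values.T.ravel().copy()
    out_states = [ic.values.copy()]
    out_times = [t0]
    nfev = steps = 0
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if protocol is not None:
            level = protocol_level(0.5 * (a + b), protocol)
        else:
            level = 0.0
        requested = t_out[(t_out > a) & (t_out <= b)]
        t_eval = np.union1d(requested, [b])
        sol = solve_ivp(
            make_rhs(level), (a, b), y, t_eval=t_eval,
            method=method, rtol=rtol, atol=atol, **options,
        )
        if not sol.success:
            raise SolverFailure(
                f"integration failed at t = {sol.t[-1] if len(sol.t) else a:.4f} "
                f"(segment [{a:.4f}, {b:.4f}]): {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise SolverFailure(f"non-finite state in segment [{a:.4f}, {b:.4f}]")
        nfev += sol.nfev
        steps += len(sol.t)
        requested_set = set(np.round(requested, 12))
        for k, tk in enumerate(sol.t):
            if np.round(tk, 12) in requested_set:
                out_states.append(sol.y[:, k].reshape(n, nf).T.copy())
                out_times.append(float(tk))
        y = sol.y[:, -1].copy()

    states = np.array(out_states)
    worst = states.min()
    # solver-consistent undershoot policy: anything the stepper cannot be
    # expected to resolve (O(atol)) is clipped and counted; worse is an error
    hard_tol = max(NEGATIVITY_TOL, 10.0 * atol)
    if worst < -hard_tol:
        raise SolverFailure(
            f"negative undershoot {worst:.3e} exceeds tolerance {hard_tol:g}"
        )
    clipped = int(np.count_nonzero(states < 0))
    states = np.maximum(states, 0.0)
    diag = {"nfev": nfev, "steps": steps, "segments": len(seg_edges) - 1,
            "clipped": clipped, "method": method, "rtol": rtol, "atol": atol}
    return Trajectory(times=np.array(out_times), states=states, grid=grid,
                      diagnostics=diag)
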