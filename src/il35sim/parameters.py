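"""Model constants, scenario presets, scaling transforms, and calibration helpers.

The model tracks ten radially symmetric fields in a tumor sphere of radius
``R_domain``:

==========  =====================================  =================
symbol      meaning                                dimensional unit
==========  =====================================  =================
``c``       tumor cell density                     g/cm^3
``q``       M-CSF concentration                    g/cm^3
``M``       MDSC density                           g/cm^3
``rho``     IL-35 concentration                    g/cm^3
``R_treg``  regulatory T cell density              g/cm^3
``beta``    TGF-beta concentration                 g/cm^3
``T``       activated CD8+ T cell density          g/cm^3
``h``       VEGF concentration                     g/cm^3
``e``       endothelial cell density               g/cm^3
``w``       oxygen concentration                   g/cm^3
==========  =====================================  =================

All constants live in ``data/parameters.yaml`` (single source of truth; code
never hard-codes a value).  Each entry records the dimensional value, the
frozen dimensionless value under the default :class:`ScalingSystem`, the unit,
and the parameter-table group it belongs to, so the transcription is
auditable.  The two scenario presets — ``"J558-IL-35"`` (IL-35-transfected
plasmacytoma) and ``"J558-Ctrl"`` (control) — differ only in
``lambda_rho_c``, the tumor-cell IL-35 production rate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "FIELDS",
    "ModelParameters",
    "ScalingSystem",
    "ParameterError",
    "InfeasibleCalibration",
    "SCENARIOS",
    "load_scenario",
    "load_parameter_table",
    "scale_factor",
    "nondimensionalize",
    "redimensionalize",
    "audit_parameter_table",
    "calibrate_mdsc_production",
    "calibrate_il35_production",
]

#: Canonical field order used everywhere (state arrays, exports, plots).
FIELDS = ("c", "q", "M", "rho", "R_treg", "beta", "T", "h", "e", "w")

SCENARIOS = ("J558-IL-35", "J558-Ctrl")

_DATA_PACKAGE = "il35sim.data"


class ParameterError(ValueError):
    """A parameter set violates positivity, ordering, or schema constraints."""


class InfeasibleCalibration(ValueError):
    """The requested calibration target cannot be met by the model form."""


# --------------------------------------------------------------------------
# Scale exponents: dimensional value = dimensionless value * prod(ref**exp).
# Reference symbols: L (length), t (time), and one magnitude per field plus
# the drug concentration scale "A".  A parameter absent from this map is
# dimensionless (counts, fractions, lumping ratios).
# --------------------------------------------------------------------------
SCALE_EXPONENTS: dict[str, dict[str, int]] = {
    # tumor cell equation
    "D_c": {"L": 2, "t": -1},
    "c_max": {"c": 1},
    "lambda_c": {"t": -1},
    "d_n": {"t": -1},
    "d_c": {"t": -1},
    "eta": {"t": -1, "T": -1},
    "w_nec": {"w": 1},
    "w_hyp": {"w": 1},
    "w_normal": {"w": 1},
    # M-CSF
    "D_q": {"L": 2, "t": -1},
    "s_q": {"q": 1, "c": -1, "t": -1},
    "d_q": {"t": -1},
    # MDSC
    "s_M": {"M": 1, "t": -1},
    "lambda_M_rho": {"M": 1, "t": -1},
    "K_rho": {"rho": 1},
    "D_M": {"L": 2, "t": -1},
    "chi_M": {"L": 2, "t": -1, "q": -1},
    "lambda_MQ": {"t": -1},
    "M_0": {"M": 1},
    "K_q": {"q": 1},
    "d_M": {"t": -1},
    # IL-35
    "D_rho": {"L": 2, "t": -1},
    "lambda_rho_c": {"rho": 1, "c": -1, "t": -1},
    "lambda_rho_R": {"rho": 1, "R_treg": -1, "t": -1},
    "lambda_rho_M": {"rho": 1, "M": -1, "t": -1},
    "d_rho": {"t": -1},
    # Treg
    "D_R": {"L": 2, "t": -1},
    "lambda_RM": {"R_treg": 1, "t": -1},
    "K_M": {"M": 1},
    "lambda_R_beta": {"R_treg": 1, "t": -1},
    "K_beta": {"beta": 1},
    "d_R": {"t": -1},
    # TGF-beta
    "D_beta": {"L": 2, "t": -1},
    "lambda_beta_c": {"beta": 1, "c": -1, "t": -1},
    "lambda_beta_R": {"beta": 1, "R_treg": -1, "t": -1},
    "d_beta": {"t": -1},
    # CD8+ T
    "D_T": {"L": 2, "t": -1},
    "chi_T": {"L": 2, "t": -1, "M": -1},
    "lambda_T12": {"T": 1, "t": -1},
    "k_10M": {},
    "k_MCP": {},
    "k_12M": {},
    "K_T1": {"M": 1},
    "K_T2": {"M": 1},
    "d_T": {"t": -1},
    # VEGF
    "D_h": {"L": 2, "t": -1},
    "lambda_hc": {"h": 1, "c": -1, "t": -1},
    "K_rho_h": {"rho": 1},
    "eps_c": {},
    "lambda_hM": {"h": 1, "M": -1, "t": -1},
    "K_q_h": {"q": 1},
    "eps_M": {},
    "d_h": {"t": -1},
    "w_star": {"w": 1},
    # EC
    "D_e": {"L": 2, "t": -1},
    "chi_e": {"L": 2, "t": -1, "h": -1},
    "lambda_e": {"t": -1},
    "e_max": {"e": 1},
    "K_h": {"h": 1},
    "h_star": {"h": 1},
    # oxygen
    "lambda_w": {"t": -1, "e": -1},
    "D_w": {"L": 2, "t": -1},
    "k_wT": {"t": -1, "T": -1},
    "k_wM": {"t": -1, "M": -1},
    "k_wR": {"t": -1, "R_treg": -1},
    "k_wc": {"t": -1, "c": -1},
    # boundary / environment
    "gamma_e": {"L": 1, "t": -1},
    "gamma_w": {"L": 1, "t": -1},
    "e_normal": {"e": 1},
    "w_0": {"w": 1},
    # anti-IL-35 drug coupling (Eq.-14/15-style extension)
    "mu_A": {"t": -1, "A": -1},
    "ell_A": {"L": 1},
    # domain / horizon / initialization
    "R_domain": {"L": 1},
    "t_final": {"t": 1},
    "c_init_amp": {"c": 1},
    "r_init_width": {"L": 1},
    "m_init_width": {"L": 1},
    "init_treg_frac": {},
    "e_init_frac": {},
    "w_init_frac": {},
}


@dataclass(frozen=True)
class ScalingSystem:
    """Reference magnitudes used to nondimensionalize the model.

    ``length`` is the tumor-sphere radius scale (cm), ``time`` the kinetic
    time scale (day), ``refs`` one reference magnitude per field (g/cm^3)
    plus the drug concentration scale under key ``"A"``.
    """

    length: float = 0.5
    time: float = 1.0
    refs: Mapping[str, float] = field(
        default_factory=lambda: {
            "c": 0.8,
            "q": 1.0e-8,
            "M": 0.05,
            "rho": 1.0e-9,
            "R_treg": 0.05,
            "beta": 1.0e-9,
            "T": 0.05,
            "h": 1.0e-9,
            "e": 0.05,
            "w": 6.0e-6,
            "A": 1.0e-8,
        }
    )

    def __post_init__(self) -> None:
        if self.length <= 0 or self.time <= 0:
            raise ParameterError("scale factors must be strictly positive")
        for key, val in self.refs.items():
            if not (val > 0 and math.isfinite(val)):
                raise ParameterError(f"non-positive reference magnitude for {key!r}")
        missing = set(FIELDS + ("A",)) - set(self.refs)
        if missing:
            raise ParameterError(f"missing reference magnitudes: {sorted(missing)}")


def scale_factor(name: str, scaling: ScalingSystem) -> float:
    """Product of reference magnitudes converting dimensionless -> dimensional."""
    try:
        exponents = SCALE_EXPONENTS[name]
    except KeyError:
        raise ParameterError(f"unknown parameter {name!r}") from None
    factor = 1.0
    for sym, exp in exponents.items():
        if sym == "L":
            base = scaling.length
        elif sym == "t":
            base = scaling.time
        else:
            base = scaling.refs[sym]
        factor *= base**exp
    return factor


# --------------------------------------------------------------------------
# Parameter container
# --------------------------------------------------------------------------

_THRESHOLD_EXEMPT = {"scenario", "dimensionless"}
# parameters allowed to be zero (fractions that may legitimately vanish)
_MAY_BE_ZERO: set[str] = set()


@dataclass
class ModelParameters:
    """All rate, diffusion, threshold, and geometry constants of the model.

    Values are dimensional (cm, day, g/cm^3) unless ``dimensionless`` is
    True, in which case they are scaled by the :class:`ScalingSystem` that
    produced them.  Construct via :func:`load_scenario`; mutate via
    :meth:`replace` so validation always reruns.
    """

    # --- tumor cell equation ---
    D_c: float
    c_max: float
    lambda_c: float
    d_n: float
    d_c: float
    eta: float
    w_nec: float
    w_hyp: float
    w_normal: float
    # --- M-CSF ---
    D_q: float
    s_q: float
    d_q: float
    # --- MDSC ---
    s_M: float
    lambda_M_rho: float
    K_rho: float
    D_M: float
    chi_M: float
    lambda_MQ: float
    M_0: float
    K_q: float
    d_M: float
    # --- IL-35 ---
    D_rho: float
    lambda_rho_c: float
    lambda_rho_R: float
    lambda_rho_M: float
    d_rho: float
    # --- Treg ---
    D_R: float
    lambda_RM: float
    K_M: float
    lambda_R_beta: float
    K_beta: float
    d_R: float
    # --- TGF-beta ---
    D_beta: float
    lambda_beta_c: float
    lambda_beta_R: float
    d_beta: float
    # --- CD8+ T ---
    D_T: float
    chi_T: float
    lambda_T12: float
    k_10M: float
    k_MCP: float
    k_12M: float
    K_T1: float
    K_T2: float
    d_T: float
    # --- VEGF ---
    D_h: float
    lambda_hc: float
    K_rho_h: float
    eps_c: float
    lambda_hM: float
    K_q_h: float
    eps_M: float
    d_h: float
    w_star: float
    # --- EC ---
    D_e: float
    chi_e: float
    lambda_e: float
    e_max: float
    K_h: float
    h_star: float
    # --- oxygen ---
    lambda_w: float
    D_w: float
    k_wT: float
    k_wM: float
    k_wR: float
    k_wc: float
    # --- boundary / environment ---
    gamma_e: float
    gamma_w: float
    e_normal: float
    w_0: float
    # --- drug coupling ---
    mu_A: float
    ell_A: float
    # --- domain / horizon / initialization ---
    R_domain: float
    t_final: float
    c_init_amp: float
    r_init_width: float
    m_init_width: float
    init_treg_frac: float
    e_init_frac: float
    w_init_frac: float
    # --- metadata ---
    scenario: str = "custom"
    dimensionless: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in dc_fields(self):
            if f.name in _THRESHOLD_EXEMPT:
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ParameterError(f"parameter {f.name} is not a finite number: {v!r}")
            if v <= 0 and f.name not in _MAY_BE_ZERO:
                raise ParameterError(f"parameter {f.name} must be strictly positive, got {v}")
        if not (0 < self.w_nec < self.w_hyp < self.w_normal):
            raise ParameterError(
                "oxygen thresholds must satisfy 0 < w_nec < w_hyp < w_normal"
            )
        if not (0 < self.w_star < self.w_normal):
            raise ParameterError("w_star must lie in (0, w_normal)")
        if self.eps_c >= 1 or self.eps_M >= 1:
            raise ParameterError("baseline VEGF ratios eps_c, eps_M must be < 1")
        if self.e_normal >= self.e_max:
            raise ParameterError("e_normal must be below e_max")
        for name in ("init_treg_frac", "e_init_frac", "w_init_frac", "c_init_amp"):
            pass  # positivity already enforced; fractions may exceed 1 only for amp
        if self.e_init_frac > 1 or self.w_init_frac > 1:
            raise ParameterError("initial boundary fractions must be <= 1")

    def as_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("scenario")
        d.pop("dimensionless")
        return d

    def replace(self, **overrides: float) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------


def _read_yaml(path: str | Path | None) -> dict:
    if path is None:
        text = resources.files(_DATA_PACKAGE).joinpath("parameters.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def load_parameter_table(path: str | Path | None = None) -> dict[str, dict]:
    """Raw parameter table: name -> {value, dimensionless, unit, table, description}.

    ``value`` is either a float or a scenario -> float mapping (only
    ``lambda_rho_c`` uses the latter).
    """
    table = _read_yaml(path)["parameters"]
    unknown = set(table) - set(SCALE_EXPONENTS)
    if unknown:
        raise ParameterError(f"parameter table has unknown entries: {sorted(unknown)}")
    missing = set(SCALE_EXPONENTS) - set(table)
    if missing:
        raise ParameterError(f"parameter table is missing entries: {sorted(missing)}")
    return table


def load_scenario(
    name: str = "J558-IL-35",
    overrides: Mapping[str, float] | None = None,
    path: str | Path | None = None,
) -> ModelParameters:
    """Load a validated dimensional parameter set for a named scenario.

    Parameters
    ----------
    name:
        ``"J558-IL-35"``, ``"J558-Ctrl"``, or the name recorded in a custom
        table; presets differ only in the tumor IL-35 production rate.
    overrides:
        Optional name -> dimensional value replacements, validated after
        substitution.
    path:
        Optional custom parameter table (same YAML schema as the shipped one).
    """
    if name not in SCENARIOS and path is None:
        raise ParameterError(
            f"unknown scenario {name!r}; expected one of {SCENARIOS} "
            "(pass path= for a custom table)"
        )
    table = load_parameter_table(path)
    values: dict[str, float] = {}
    for key, entry in table.items():
        v = entry["value"]
        if isinstance(v, Mapping):
            if name not in v:
                raise ParameterError(f"parameter {key} has no value for scenario {name!r}")
            v = v[name]
        values[key] = float(v)
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ParameterError(f"unknown override keys: {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})
    return ModelParameters(scenario=name, dimensionless=False, **values)


# --------------------------------------------------------------------------
# Nondimensionalization
# --------------------------------------------------------------------------


def nondimensionalize(
    p: ModelParameters, scaling: ScalingSystem | None = None
) -> ModelParameters:
    """Scale a dimensional parameter set to the dimensionless system.

    Each parameter is divided by the product of reference magnitudes given by
    its dimension exponents, so two parameters with identical units and values
    always map to identical dimensionless values.
    """
    if p.dimensionless:
        raise ParameterError("parameter set is already dimensionless")
    scaling = scaling or ScalingSystem()
    values = {
        name: val / scale_factor(name, scaling) for name, val in p.as_dict().items()
    }
    return ModelParameters(scenario=p.scenario, dimensionless=True, **values)


def redimensionalize(
    p: ModelParameters, scaling: ScalingSystem | None = None
) -> ModelParameters:
    """Exact inverse of :func:`nondimensionalize`."""
    if not p.dimensionless:
        raise ParameterError("parameter set is already dimensional")
    scaling = scaling or ScalingSystem()
    values = {
        name: val * scale_factor(name, scaling) for name, val in p.as_dict().items()
    }
    return ModelParameters(scenario=p.scenario, dimensionless=False, **values)


def audit_parameter_table(
    path: str | Path | None = None,
    scaling: ScalingSystem | None = None,
    rtol: float = 1e-9,
) -> list[str]:
    """Cross-check the dimensional and frozen dimensionless columns.

    Recomputes the dimensionless value of every entry from its dimensional
    value under the declared scaling and compares with the frozen
    ``dimensionless`` column.  Returns a list of discrepancy messages (empty
    when the table is internally consistent).
    """
    scaling = scaling or ScalingSystem()
    table = load_parameter_table(path)
    problems: list[str] = []
    for name, entry in table.items():
        dim, nondim = entry["value"], entry["dimensionless"]
        if not isinstance(dim, Mapping):
            dim, nondim = {"": dim}, {"": nondim}
        for key in dim:
            expected = float(dim[key]) / scale_factor(name, scaling)
            got = float(nondim[key])
            if not math.isclose(expected, got, rel_tol=rtol):
                problems.append(
                    f"{name}{('[' + key + ']') if key else ''}: dimensional "
                    f"{dim[key]} -> {expected:.12g}, table says {got:.12g}"
                )
    return problems


# --------------------------------------------------------------------------
# Calibration helpers (steady-state estimates of production rates)
# --------------------------------------------------------------------------


def calibrate_mdsc_production(
    ratio_obs: float,
    d_M: float,
    horizon: float,
    s_M: float = 1.0,
    saturation: float = 0.5,
) -> float:
    """Estimate the IL-35-enhanced MDSC production rate from an observed ratio.

    Uses the simplified spatially homogeneous MDSC balances for the two
    scenarios (IL-35 grows slowly, so its saturation factor is frozen at the
    time-average ``saturation``)::

        dM_ctrl/dt = s_M                              - d_M * M_ctrl
        dM_il35/dt = s_M + saturation * lambda_M_rho  - d_M * M_il35

    With the initial MDSC density neglected, both solutions share the factor
    ``(1 - exp(-d_M t)) / d_M``, so the IL-35-to-control ratio at the horizon
    is ``1 + saturation * lambda_M_rho / s_M`` and the inversion is

        ``lambda_M_rho = s_M * (ratio_obs - 1) / saturation``.

    ``d_M`` and ``horizon`` parameterize the underlying balances (and the ODE
    cross-check in the tests); the closed form is independent of them because
    the exponential transients cancel in the ratio.
    """
    for name, v in (("ratio_obs", ratio_obs), ("d_M", d_M), ("horizon", horizon),
                    ("s_M", s_M), ("saturation", saturation)):
        if not math.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v!r}")
    if ratio_obs < 1:
        raise ParameterError("ratio_obs must be >= 1 (IL-35 enhances MDSC production)")
    if d_M <= 0 or horizon <= 0 or s_M <= 0 or not (0 < saturation <= 1):
        raise ParameterError("d_M, horizon, s_M must be positive; saturation in (0, 1]")
    return s_M * (ratio_obs - 1.0) / saturation


def _il35_forward(lam: float, c_bar: float, d_rho: float, t: float) -> float:
    """Saturating-exponential IL-35 build-up with constant tumor density."""
    return lam * c_bar / d_rho * (1.0 - math.exp(-d_rho * t))


def calibrate_il35_production(
    rho_target: float,
    c_bar: float,
    d_rho: float,
    t: float,
    lambda_max: float | None = None,
) -> float:
    """Invert ``rho(t) = (lambda c_bar / d_rho)(1 - exp(-d_rho t))`` for lambda.

    ``rho_target`` is the IL-35 concentration observed at time ``t`` when a
    constant tumor density ``c_bar`` is the only IL-35 source.  If
    ``lambda_max`` is given and the required production rate exceeds it, the
    target is unattainable and :class:`InfeasibleCalibration` is raised.
    """
    for name, v in (("rho_target", rho_target), ("c_bar", c_bar),
                    ("d_rho", d_rho), ("t", t)):
        if not (math.isfinite(v) and v > 0):
            raise ParameterError(f"{name} must be positive and finite, got {v!r}")
    lam = d_rho * rho_target / (c_bar * (1.0 - math.exp(-d_rho * t)))
    if lambda_max is not None and lam > lambda_max:
        raise InfeasibleCalibration(
            f"target rho({t}) = {rho_target} needs lambda = {lam:.6g} "
            f"> lambda_max = {lambda_max:.6g} "
            f"(asymptote {_il35_forward(lambda_max, c_bar, d_rho, math.inf):.6g})"
        )
    return lam


def _mdsc_scenario_ratio_ode(
    lambda_M_rho: float,
    d_M: float,
    horizon: float,
    s_M: float,
    saturation: float,
) -> float:
    """Numerically integrate the simplified two-ODE MDSC system; testing oracle."""

    def rhs(_t, y):
        m_ctrl, m_il35 = y
        return [s_M - d_M * m_ctrl, s_M + saturation * lambda_M_rho - d_M * m_il35]

    sol = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0], rtol=1e-10, atol=1e-14)
    return sol.y[1, -1] / sol.y[0, -1]


def _il35_calibration_bracket_oracle(
    rho_target: float, c_bar: float, d_rho: float, t: float
) -> float:
    """Brute-force root-finding inversion of the forward formula; testing oracle."""
    lo, hi = 1e-30, 1.0
    while _il35_forward(hi, c_bar, d_rho, t) < rho_target:
        hi *= 10.0
    return brentq(lambda lam: _il35_forward(lam, c_bar, d_rho, t) - rho_target, lo, hi,
                  xtol=1e-300, rtol=1e-14)
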