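"""Latin hypercube sampling and PRCC global sensitivity of drug efficacy.

The analysis perturbs the estimated/important dimensional rates (shipped in
``data/sensitivity_design.csv``: name, min, baseline, max, unit — every range
half-to-twofold of baseline except the tumor IL-35 production rate, which
spans the control value up to far above the transfected baseline), draws a
Latin hypercube over the boxes, and for each sample simulates the model with
and without continuous anti-IL-35 dosing.  The output is the efficacy ratio
(treated / untreated tumor burden at the horizon; smaller = more effective
drug).  Sensitivity is summarized by partial rank correlation coefficients:
rank-transform every column, regress both the target parameter's ranks and
the output ranks on all remaining parameters, and correlate the residuals
(the two-residual formulation of Marino et al.); p-values come from the
t-transform with N - 2 - (k - 1) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observables import efficacy_ratio
from .radial_pde import SolverFailure
from .runlib import simulate_scenario
from .treatment import TreatmentProtocol

__all__ = [
    "SensitivityDesign",
    "SensitivityResult",
    "load_design",
    "latin_hypercube",
    "run_design",
    "prcc",
]

_DATA_PACKAGE = "il35sim.data"
#: runs aborting in more than this fraction of samples invalidate the analysis
MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class SensitivityDesign:
    """Parameter names with [min, max] ranges and baselines."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    baseline: np.ndarray
    units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.names)
        for arr_name in ("lower", "upper", "baseline"):
            if len(getattr(self, arr_name)) != k:
                raise ValueError(f"{arr_name} length mismatch with names")
        if not np.all((self.lower < self.baseline) & (self.baseline < self.upper)):
            raise ValueError("each row must satisfy min < baseline < max")

    @property
    def k(self) -> int:
        return len(self.names)


def load_design(path: str | Path | None = None) -> SensitivityDesign:
    """Load the shipped (or a custom) sensitivity design table."""
    if path is None:
        with resources.files(_DATA_PACKAGE).joinpath("sensitivity_design.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return SensitivityDesign(
        names=tuple(df["name"]),
        lower=df["min"].to_numpy(float),
        upper=df["max"].to_numpy(float),
        baseline=df["baseline"].to_numpy(float),
        units=tuple(df["unit"]),
    )


def latin_hypercube(design: SensitivityDesign, N: int, seed: int) -> np.ndarray:
    """N x k Latin hypercube sample over the design boxes.

    Each column places exactly one point, uniformly jittered, in each of the
    N equal-width strata of that parameter's range; strata are assigned by an
    independent random permutation per column.  Fully reproducible under
    ``seed``.
    """
    if N < design.k + 2:
        raise ValueError("need at least k + 2 samples for the PRCC regressions")
    rng = np.random.default_rng(seed)
    u = (rng.permuted(np.tile(np.arange(N), (design.k, 1)), axis=1).T
         + rng.uniform(size=(N, design.k))) / N
    return design.lower + u * (design.upper - design.lower)


def run_design(
    samples: np.ndarray,
    base_scenario: str = "J558-IL-35",
    design: SensitivityDesign | None = None,
    horizon: float = 56.0,
    strength: float = 10.0,
    n_cells: int = 24,
    simulator: Callable[..., float] | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> tuple[np.ndarray, list[int]]:
    """Efficacy ratio for every sample row: continuous dosing vs no drug.

    For each row the perturbed dimensional parameters override the scenario
    baseline and the model is simulated twice — once under continuous
    anti-IL-35 at ``strength`` for ``horizon`` days, once untreated — and the
    tumor-burden ratio at the horizon is recorded.  Failed rows are returned
    as NaN together with their indices, never silently dropped; solver aborts
    beyond the ``MAX_FAILURE_FRACTION`` quota raise, while rows whose
    untreated tumor goes extinct (ratio undefined) are recorded without
    counting toward the quota.

    ``simulator(overrides, protocol) -> Trajectory`` can replace the full
    model (used by the tests with a cheap stand-in).
    """
    samples = np.asarray(samples, dtype=float)
    design = design or load_design()
    if samples.ndim != 2 or samples.shape[1] != design.k:
        raise ValueError("samples must be N x k for the design")
    proto = TreatmentProtocol(mode="continuous", strength=strength, duration=horizon)
    none = TreatmentProtocol(mode="none")

    outputs = np.full(len(samples), np.nan)
    failures: list[int] = []
    aborts = 0
    for i, row in enumerate(samples):
        overrides = dict(zip(design.names, row))
        try:
            if simulator is not None:
                outputs[i] = simulator(overrides, proto)
            else:
                common = dict(scenario=base_scenario, t_out=[horizon],
                              n_cells=n_cells, overrides=overrides,
                              rtol=rtol, atol=atol)
                traj_drug = simulate_scenario(protocol=proto, **common)
                traj_none = simulate_scenario(protocol=none, **common)
                outputs[i] = efficacy_ratio(traj_drug, traj_none, horizon)
        except ZeroDivisionError:
            # tumor extinct in the untreated arm: a valid simulation outcome
            # whose ratio is undefined; recorded and excluded pairwise, but it
            # is not a solver abort and does not count toward the abort quota
            failures.append(i)
        except (SolverFailure, ValueError) as exc:
            failures.append(i)
            aborts += 1
            if aborts > MAX_FAILURE_FRACTION * len(samples):
                raise SolverFailure(
                    f"{aborts} of {len(samples)} sensitivity runs aborted; "
                    f"last error at row {i}: {exc}"
                ) from exc
    return outputs, failures


@dataclass
class SensitivityResult:
    """Per-parameter PRCC and p-value for one scalar model output."""

    names: tuple[str, ...]
    prcc: np.ndarray
    p_value: np.ndarray
    N: int
    output: str = "efficacy_ratio"
    failures: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.names, "PRCC": self.prcc, "p_value": self.p_value}
        )


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0, method="average")


def _residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xi = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return y - Xi @ coef


def prcc(
    samples: np.ndarray,
    outputs: np.ndarray,
    names: Sequence[str] | None = None,
    output_name: str = "efficacy_ratio",
) -> SensitivityResult:
    """Partial rank correlation of each sample column with the output.

    Rows with non-finite output (failed simulations) are excluded pairwise
    and recorded in the result.  Raises on constant columns or on a
    rank-deficient control regression.
    """
    samples = np.asarray(samples, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if samples.ndim != 2 or len(outputs) != len(samples):
        raise ValueError("samples must be N x k with one output per row")
    keep = np.isfinite(outputs)
    failures = list(np.flatnonzero(~keep))
    samples, outputs = samples[keep], outputs[keep]
    N, k = samples.shape
    if N <= k + 2:
        raise ValueError(f"need more than k + 2 = {k + 2} usable samples, have {N}")
    if np.any(np.ptp(samples, axis=0) == 0.0):
        raise ValueError("constant sample column; PRCC undefined")
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(k))

    rs = _rank(samples)
    ry = _rank(outputs)
    dof = N - 2 - (k - 1)
    if dof < 1:
        raise ValueError("not enough samples for the partial-correlation dof")
    vals = np.empty(k)
    pvals = np.empty(k)
    for j in range(k):
        others = np.delete(rs, j, axis=1)
        res_x = _residuals(rs[:, j], others)
        res_y = _residuals(ry, others)
        denom = math.sqrt(float(res_x @ res_x) * float(res_y @ res_y))
        if denom == 0.0:
            raise ValueError(f"rank-deficient regression for parameter {names[j]!r}")
        r = float(res_x @ res_y) / denom
        r = min(1.0, max(-1.0, r))
        vals[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            tstat = r * math.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * stats.t.sf(abs(tstat), dof)
    return SensitivityResult(names=names, prcc=vals, p_value=pvals, N=N,
                             output=output_name, failures=failures)
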