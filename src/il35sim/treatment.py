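"""Anti-IL-35 drug: spatial penetration profile, dosing schedules, IL-35 sink.

The drug blocks IL-35 and enters the model only as the sink ``-mu_A rho A``
in the IL-35 balance.  Its spatial profile is a static pharmacokinetic
assumption — the concentration decays exponentially from the tumor rim
(where the drug arrives) toward the center with penetration depth
``ell_A``.  Three schedules are compared at equal total dose:

* ``none`` — A = 0 always;
* ``continuous`` — fixed level A0 throughout the treatment window;
* ``intermittent`` — double level 2*A0, one week on / one week off.

The default window is 56 days (eight weeks, "two months" in the week-aligned
calendar) so the alternating schedule tiles it exactly and the two active
schedules deliver identical time-integrated dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters
from .radial_pde import RadialGrid

__all__ = [
    "TreatmentProtocol",
    "drug_spatial_profile",
    "protocol_level",
    "protocol_breakpoints",
    "il35_sink",
]

MODES = ("none", "continuous", "intermittent")
DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class TreatmentProtocol:
    """Dosing mode, strength, and schedule for the anti-IL-35 drug.

    ``strength`` is the continuous-equivalent level A0 (dimensionless drug
    units); the intermittent mode doses at 2*A0 during on-weeks so the total
    delivered dose matches the continuous schedule.  ``duration`` (days)
    should be an even number of ``on_period`` + ``off_period`` blocks for the
    equal-dose identity to be exact.
    """

    mode: str = "none"
    strength: float = 0.0
    duration: float = 56.0
    on_period: float = DAYS_PER_WEEK
    off_period: float = DAYS_PER_WEEK

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown dosing mode {self.mode!r}; expected {MODES}")
        if self.strength < 0:
            raise ValueError("dose strength must be nonnegative")
        if self.mode != "none":
            if self.duration <= 0:
                raise ValueError("active protocols need a positive duration")
            if self.on_period <= 0 or self.off_period <= 0:
                raise ValueError("on/off periods must be positive")


def drug_spatial_profile(
    grid: RadialGrid, level: float, p: ModelParameters
) -> np.ndarray:
    """Drug concentration along the radius at instantaneous dose ``level``.

    ``A(r) = level * exp(-(R - r) / ell_A)`` — maximal at the rim r = R where
    the drug is delivered, decaying toward the center with penetration depth
    ``ell_A``; monotone nondecreasing in r.
    """
    if level < 0:
        raise ValueError("dose level must be nonnegative")
    return level * np.exp(-(grid.R - grid.centers) / p.ell_A)


def protocol_level(t: float, proto: TreatmentProtocol) -> float:
    """Instantaneous dose level at time ``t`` (days).

    Continuous: A0 on [0, duration], 0 after.  Intermittent: 2*A0 during the
    on-window of each on+off cycle within the duration, 0 otherwise.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    if proto.mode == "none" or proto.strength == 0.0:
        return 0.0
    if t > proto.duration:
        return 0.0
    if proto.mode == "continuous":
        return proto.strength
    # intermittent
    cycle = proto.on_period + proto.off_period
    phase = t % cycle
    boost = cycle / proto.on_period  # 2 for equal on/off periods
    return boost * proto.strength if phase < proto.on_period else 0.0


def protocol_breakpoints(proto: TreatmentProtocol) -> np.ndarray:
    """Dose-switching instants; the integrator restarts at each of them."""
    if proto.mode == "none" or proto.strength == 0.0:
        return np.array([])
    if proto.mode == "continuous":
        return np.array([0.0, proto.duration])
    cycle = proto.on_period + proto.off_period
    edges = [0.0]
    t = 0.0
    while t < proto.duration:
        edges.append(min(t + proto.on_period, proto.duration))
        t += cycle
        if t < proto.duration:
            edges.append(t)
    edges.append(proto.duration)
    return np.unique(edges)


def il35_sink(rho, A, p: ModelParameters):
    """IL-35 removal rate by the drug: ``-mu_A * rho * A`` (always <= 0)."""
    rho = np.asarray(rho, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(rho < 0) or np.any(A < 0):
        raise ValueError("rho and A must be nonnegative")
    return -p.mu_A * rho * A
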