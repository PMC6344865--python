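"""Pressure thermodynamics: equilibrium constants and the transition volume.

For a two-state hairpin the unfolding equilibrium constant is
Keq = F_open / F_closed, and its pressure dependence at constant temperature
gives the transition volume through

    (d ln Keq / d p)_T = -dV / (R T),

so dV (cm^3 mol^-1) is read off the slope of an ordinary least-squares fit of
ln Keq against pressure (internally in Pa; 1 bar = 1e5 Pa exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mixture import StateFractions
from .scheme import BAR_TO_PA, CM3_TO_M3, R_GAS


@dataclass(frozen=True)
class PressurePoint:
    """One pressure condition: state fractions and the derived Keq."""

    pressure: float  # bar
    fractions: StateFractions
    keq: float


@dataclass(frozen=True)
class VolumeFit:
    """Transition volume from the ln Keq vs p regression."""

    delta_v: float  # cm^3 mol^-1
    delta_v_se: float
    intercept: float  # ln Keq extrapolated to p = 0
    temperature: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a volume fit needs at least 2 points")
        if self.delta_v_se < 0:
            raise ValueError("standard error must be >= 0")


def equilibrium_constant(f: StateFractions) -> float:
    """Keq = F_open / F_closed for the closed-to-open (unfolding) transition."""
    if f.f_closed <= 0:
        raise ValueError("fully open: Keq undefined (F_closed = 0)")
    if f.f_open == 0:
        warnings.warn(
            "F_open = 0: Keq = 0 cannot enter the ln Keq regression",
            stacklevel=2,
        )
        return 0.0
    return f.f_open / f.f_closed


def pressure_point(pressure: float, fractions: StateFractions) -> PressurePoint:
    return PressurePoint(
        pressure=pressure, fractions=fractions, keq=equilibrium_constant(fractions)
    )


def fit_volume(
    points: Sequence[PressurePoint], temperature: float = 298.15
) -> VolumeFit:
    """OLS of ln Keq on pressure; dV = -slope * R * T in cm^3 mol^-1.

    Points with Keq <= 0 are excluded (and counted).  The default
    temperature is 298.15 K (25 C); unweighted regression matches the plain
    linear fits used for this quantity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    usable = [pt for pt in points if pt.keq > 0]
    n_excluded = len(points) - len(usable)
    if len(usable) < 2:
        raise ValueError("need at least 2 points with Keq > 0")
    p_pa = np.array([pt.pressure for pt in usable]) * BAR_TO_PA
    if np.ptp(p_pa) == 0:
        raise ValueError("pressures must not all be equal")
    ln_keq = np.log([pt.keq for pt in usable])
    if len(usable) == 2:
        slope = (ln_keq[1] - ln_keq[0]) / (p_pa[1] - p_pa[0])
        intercept = ln_keq[0] - slope * p_pa[0]
        slope_se = 0.0
    else:
        res = stats.linregress(p_pa, ln_keq)
        slope, intercept, slope_se = res.slope, res.intercept, res.stderr
    delta_v_m3 = -slope * R_GAS * temperature
    se_m3 = slope_se * R_GAS * temperature
    return VolumeFit(
        delta_v=delta_v_m3 / CM3_TO_M3,
        delta_v_se=se_m3 / CM3_TO_M3,
        intercept=float(intercept),
        temperature=temperature,
        n_points=len(usable),
        n_excluded=n_excluded,
    )
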