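"""Van't Hoff analysis of the binding constant's temperature dependence.

Assuming dH and dS constant over the fitted range,

    ln Kb = -dH/(R*T) + dS/R

so OLS of ln Kb on 1/T yields dH = -R*slope and dS = R*intercept. The
Gibbs energy is then available by two routes whose agreement is an
internal-consistency check: (a) dG = -RT ln Kb at each temperature and
(b) dG = dH - T*dS from the fitted parameters. The sign pattern of
(dH, dS) classifies the dominant non-covalent force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .binding import gibbs_from_kb
from .constants import GAS_CONSTANT
from .errors import DomainError, InsufficientDataError

#: |dH| (kJ/mol) at or below which the enthalpy counts as "approximately
#: zero" for the electrostatic rule — roughly 1.5 RT at 298 K.
DELTA_H_ZERO_BAND = 4.0


@dataclass(frozen=True)
class KbSeries:
    """Binding constants at several temperatures, input to the van't Hoff fit."""

    entries: tuple  # ((temperature K, kb M^-1), ...)
    source: str = ""

    def __post_init__(self):
        entries = tuple((float(t), float(k)) for t, k in self.entries)
        temps = [t for t, _ in entries]
        if len(set(temps)) != len(temps):
            raise DomainError("duplicate temperatures in Kb series")
        if any(t <= 0 for t in temps):
            raise DomainError("temperatures must be positive (kelvin)")
        if any(k <= 0 for _, k in entries):
            raise DomainError("all kb must be positive")
        object.__setattr__(self, "entries", entries)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])

    @property
    def kb_values(self) -> np.ndarray:
        return np.array([k for _, k in self.entries])


@dataclass(frozen=True)
class ThermoParams:
    """Fitted van't Hoff parameters with per-temperature Gibbs energies."""

    delta_h: float   # kJ/mol
    delta_s: float   # J mol^-1 K^-1
    fit_r: float     # Pearson r of ln Kb vs 1/T (nan for a 2-point fit)
    per_temperature: tuple  # ((T, dG_a via -RT ln Kb, dG_b via dH - T dS), ...)
    gas_constant: float = GAS_CONSTANT
    exact_two_point: bool = False


class ForceLabel(Enum):
    VDW_OR_HBOND = "vdw_or_hbond"
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"
    HYDROPHOBIC_PLUS_HBOND = "hydrophobic_plus_hbond"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ForceVerdict:
    label: ForceLabel
    rationale: str


def vant_hoff_fit(series: KbSeries) -> ThermoParams:
    """OLS of ln Kb on 1/T; dH = -R*slope (kJ/mol), dS = R*intercept (J/mol/K)."""
    n = len(series.entries)
    if n < 2:
        raise InsufficientDataError("van't Hoff fit needs >= 2 temperatures")
    x = 1.0 / series.temperatures
    y = np.log(series.kb_values)
    exact = n == 2
    if exact:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        fit_r = float("nan")  # undefined through two points; flagged
    else:
        res = stats.linregress(x, y)
        slope, intercept, fit_r = res.slope, res.intercept, float(res.rvalue)
    delta_h = -GAS_CONSTANT * slope / 1000.0
    delta_s = GAS_CONSTANT * intercept
    per_t = tuple(
        (t, gibbs_from_kb(k, t), gibbs_from_thermo(delta_h, delta_s, t))
        for t, k in series.entries
    )
    return ThermoParams(delta_h=float(delta_h), delta_s=float(delta_s),
                        fit_r=fit_r, per_temperature=per_t,
                        exact_two_point=exact)


def gibbs_from_thermo(delta_h: float, delta_s: float, temperature: float) -> float:
    """dG = dH - T*dS with dH in kJ/mol, dS in J mol^-1 K^-1; returns kJ/mol."""
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return delta_h - temperature * delta_s / 1000.0


def classify_forces(delta_h: float, delta_s: float,
                    *, h_zero_band: float = DELTA_H_ZERO_BAND) -> ForceVerdict:
    """Dominant-force call from the signs of dH (kJ/mol) and dS (J/mol/K).

    Both negative: van der Waals and/or hydrogen bonding. Both positive:
    hydrophobic. dS > 0 with dH approximately zero (|dH| within
    ``h_zero_band``): electrostatic. dS > 0 with clearly negative dH:
    hydrophobic interaction plus hydrogen bonding (the exothermic term
    attributed to H-bonds, the positive entropy to hydrophobic contacts).
    """
    if not (math.isfinite(delta_h) and math.isfinite(delta_s)):
        raise DomainError("delta_h and delta_s must be finite")
    if delta_h < -h_zero_band and delta_s < 0:
        return ForceVerdict(
            ForceLabel.VDW_OR_HBOND,
            "dH < 0 and dS < 0: van der Waals forces and/or hydrogen bonding")
    if delta_h > h_zero_band and delta_s > 0:
        return ForceVerdict(
            ForceLabel.HYDROPHOBIC,
            "dH > 0 and dS > 0: hydrophobic interaction dominates")
    if abs(delta_h) <= h_zero_band and delta_s > 0:
        return ForceVerdict(
            ForceLabel.ELECTROSTATIC,
            "dH ~ 0 and dS > 0: electrostatic interaction dominates")
    if delta_h < -h_zero_band and delta_s > 0:
        return ForceVerdict(
            ForceLabel.HYDROPHOBIC_PLUS_HBOND,
            "dH < 0 with dS > 0: hydrophobic contacts plus hydrogen bonding")
    return ForceVerdict(
        ForceLabel.INDETERMINATE,
        "sign pattern matches no standard force signature")
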