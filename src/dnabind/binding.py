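"""Benesi-Hildebrand analysis of absorbance titrations.

For a 1:1 ligand-DNA complex observed through the DNA chromophore, the
Benesi-Hildebrand linearization reads

    A0 / (A - A0) = eps_D / (eps_C - eps_D)
                  + eps_D / (eps_C - eps_D) * 1 / (Kb * C)

where ``A0`` and ``A`` are the DNA absorbance without and with ligand at
concentration ``C``, ``eps_D`` and ``eps_C`` the molar extinction
coefficients of free DNA and of the complex, and ``Kb`` the association
constant. Plotting y = A0/(A - A0) against x = 1/C gives a straight line
whose intercept/slope ratio is Kb. This module performs the transform,
the ordinary-least-squares fit with its diagnostics, the Gibbs energy at
one temperature, and the hyper-/hypochromism + peak-shift evidence used
for binding-mode classification. A direct nonlinear 1:1 isotherm fit is
included as a clearly-labelled secondary cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize, stats

from .constants import GAS_CONSTANT
from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    MissingReferenceError,
    NoBindingSignalError,
)
from .peaks import refine_peak
from .types import AbsorbanceTitration

#: Minimum |A - A0| (absorbance units) for a point to enter the transform;
#: below instrument noise the ordinate A0/(A - A0) explodes.
SIGNAL_ATOL = 1e-4

#: |peak shift| (nm) at or above which a UV band counts as shifted;
#: below a typical spectrophotometer bandwidth the band is "unchanged".
UV_SHIFT_THRESHOLD_NM = 2.0

#: Minimum |dA/A0| for calling a hyper-/hypochromic direction.
UV_DIRECTION_THRESHOLD = 0.02


@dataclass(frozen=True)
class BHPoint:
    """One transformed titration point: x = 1/C (L/mol), y = A0/(A - A0)."""

    inv_ligand_conc: float
    y: float


@dataclass(frozen=True)
class BindingFit:
    """A fitted Benesi-Hildebrand line and the derived binding constant."""

    kb: float                 # M^-1, intercept/slope
    intercept: float          # eps_D/(eps_C - eps_D)
    slope: float              # intercept / Kb
    pearson_r: float          # signed correlation of the fitted line
    residual_sd: float        # SD of y-residuals, n-2 denominator
    n_points: int
    temperature: float        # K
    kb_valid: bool            # False when intercept/slope <= 0
    dropped_points: tuple = ()  # ((ligand_conc, reason), ...)

    @property
    def delta_g(self) -> float:
        """Gibbs energy of association (kJ/mol) at the fit temperature."""
        return gibbs_from_kb(self.kb, self.temperature)


def bh_transform(titration: AbsorbanceTitration, *, atol: float = SIGNAL_ATOL
                 ) -> tuple[list[BHPoint], list[tuple[float, str]]]:
    """Transform a titration to Benesi-Hildebrand coordinates.

    Returns ``(points, dropped)``; each dropped entry carries the ligand
    concentration and the reason for exclusion.
    """
    if not titration.has_reference:
        raise MissingReferenceError(
            "titration lacks a zero-ligand point defining A0")
    titration.require_fit_points(4)
    a0 = titration.a0
    points: list[BHPoint] = []
    dropped: list[tuple[float, str]] = []
    for c, a in zip(titration.ligand_conc[1:], titration.absorbance[1:]):
        delta = a - a0
        if abs(delta) < atol:
            dropped.append((float(c), "no signal change (|A - A0| below tolerance)"))
            continue
        points.append(BHPoint(1.0 / float(c), float(a0 / delta)))
    if len(points) < 3:
        raise InsufficientDataError(
            f"only {len(points)} usable points after exclusions (need >= 3)")
    return points, dropped


def fit_benesi_hildebrand(points: list[BHPoint], temperature: float,
                          dropped: tuple | list = ()) -> BindingFit:
    """Ordinary least squares of y on x = 1/C; Kb = intercept/slope."""
    if len(points) < 3:
        raise InsufficientDataError("need >= 3 points for the BH fit")
    x = np.array([p.inv_ligand_conc for p in points])
    y = np.array([p.y for p in points])
    if np.unique(x).size != x.size:
        raise DomainError("x values (1/C) must be distinct")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    scale = max(abs(y).max(), 1.0) / max(abs(x).max(), 1.0)
    if abs(slope) <= 1e3 * np.finfo(float).eps * scale:
        raise NoBindingSignalError("BH slope is zero within machine tolerance")
    resid = y - (intercept + slope * x)
    residual_sd = math.sqrt(float(resid @ resid) / (len(points) - 2))
    kb = intercept / slope
    return BindingFit(
        kb=float(kb), intercept=float(intercept), slope=float(slope),
        pearson_r=float(res.rvalue), residual_sd=residual_sd,
        n_points=len(points), temperature=float(temperature),
        kb_valid=bool(kb > 0), dropped_points=tuple(dropped),
    )


def fit_titration(titration: AbsorbanceTitration, *, atol: float = SIGNAL_ATOL
                  ) -> BindingFit:
    """Convenience composition: transform then fit, carrying drop reasons."""
    points, dropped = bh_transform(titration, atol=atol)
    return fit_benesi_hildebrand(points, titration.temperature, dropped)


def gibbs_from_kb(kb: float, temperature: float) -> float:
    """Standard Gibbs energy of association, dG = -RT ln Kb, in kJ/mol."""
    if kb <= 0:
        raise DomainError("kb must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return -GAS_CONSTANT * temperature * math.log(kb) / 1000.0


def fit_isotherm_nonlinear(titration: AbsorbanceTitration) -> dict:
    """Secondary cross-check estimator: direct nonlinear 1:1 isotherm fit.

    Fits A(C) = A0 + dA_sat * Kb*C / (1 + Kb*C) by least squares with A0
    fixed at the zero-ligand reference. This is NOT the primary estimator
    (the straight-line diagnostics r and residual SD belong to the BH
    line); it guards against pathologies of the linearization.
    """
    if not titration.has_reference:
        raise MissingReferenceError("isotherm fit needs the zero-ligand point")
    a0 = titration.a0
    c = titration.ligand_conc[1:]
    a = titration.absorbance[1:]

    def model(conc, kb, da_sat):
        return a0 + da_sat * kb * conc / (1.0 + kb * conc)

    da_guess = a[-1] - a0 if abs(a[-1] - a0) > 0 else 1e-3
    kb_guess = 1.0 / max(c[len(c) // 2], 1e-12)
    popt, _ = optimize.curve_fit(model, c, a, p0=(kb_guess, da_guess * 2),
                                 maxfev=20000)
    return {"kb": float(popt[0]), "delta_a_saturation": float(popt[1]),
            "estimator": "nonlinear-1:1-isotherm (secondary cross-check)"}


# ---------------------------------------------------------------------------
# UV evidence (hyper-/hypochromism and peak-shift rule)
# ---------------------------------------------------------------------------

class UVDirection(Enum):
    HYPERCHROMIC = "hyperchromic"
    HYPOCHROMIC = "hypochromic"
    NONE = "none"


@dataclass(frozen=True)
class UVSpectrum:
    """A UV-Vis spectrum on an increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise DomainError("wavelength and absorbance must be equal-length 1-D")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class UVEvidence:
    """Direction and band-shift evidence from the DNA 260 nm band.

    Groove binders typically leave the band position nearly unchanged
    (often with hyperchromism); intercalators produce hypochromism with a
    red shift.
    """

    direction: UVDirection
    peak_shift: float             # nm, bound minus free
    max_fractional_change: float  # (A_bound - A_free)/A_free at the free peak
    shift_reliable: bool = True
    shifted: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "shifted",
            bool(self.shift_reliable and abs(self.peak_shift) >= UV_SHIFT_THRESHOLD_NM))


def uv_evidence(free: UVSpectrum, bound: UVSpectrum | list[UVSpectrum],
                window: tuple[float, float] = (240.0, 290.0),
                *, direction_threshold: float = UV_DIRECTION_THRESHOLD
                ) -> UVEvidence:
    """Extract hyper-/hypochromism and peak shift around the DNA band.

    ``bound`` may be a single spectrum or the whole titration series; the
    highest ligand load (last spectrum) defines the reported change.
    """
    series = bound if isinstance(bound, list) else [bound]
    if not series:
        raise InsufficientDataError("no bound spectra supplied")
    top = series[-1]
    if (free.wavelength.shape != top.wavelength.shape
            or not np.allclose(free.wavelength, top.wavelength)):
        raise AlignmentError("free and bound spectra are on different grids")
    lo, hi = window
    if free.wavelength[0] > lo or free.wavelength[-1] < hi:
        raise AlignmentError("spectra do not cover the analysis window")

    peak_free, edge_free = refine_peak(free.wavelength, free.absorbance, lo, hi)
    peak_bound, edge_bound = refine_peak(top.wavelength, top.absorbance, lo, hi)
    reliable = not (edge_free or edge_bound)

    # fractional change at the free-spectrum peak sample
    mask = (free.wavelength >= lo) & (free.wavelength <= hi)
    i = np.flatnonzero(mask)[np.argmax(free.absorbance[mask])]
    a_free = free.absorbance[i]
    if a_free <= 0:
        raise DomainError("free-spectrum peak absorbance must be positive")
    frac = float((top.absorbance[i] - a_free) / a_free)

    if abs(frac) > direction_threshold:
        direction = (UVDirection.HYPERCHROMIC if frac > 0
                     else UVDirection.HYPOCHROMIC)
    else:
        direction = UVDirection.NONE
    return UVEvidence(direction=direction,
                      peak_shift=float(peak_bound - peak_free),
                      max_fractional_change=frac,
                      shift_reliable=reliable)
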