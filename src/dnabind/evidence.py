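"""Binding-mode evidence lines and their aggregation.

Four orthogonal experiments discriminate intercalation from groove and
electrostatic binding:

* viscosity — intercalation lengthens the helix and raises (eta/eta0)^(1/3);
  groove and electrostatic binding leave it flat;
* competitive fluorescence displacement — displacing ethidium bromide
  (an intercalator) signals intercalation, displacing rhodamine B (an
  AT-preferring minor-groove probe) signals minor-groove binding;
* ionic strength — absorbance sensitivity to added NaCl reveals an
  electrostatic component;
* FT-IR band shifts — base-band shifts show direct base contact, an
  AT > GC shift preference points at the (AT-rich) minor groove, and
  unshifted phosphate bands show the B-conformation is retained.

Together with the UV shift rule these feed a deterministic decision
table producing a ModeVerdict. All thresholds are artifact policy (the
source experiments are described only qualitatively); defaults sit at
roughly 2-5x typical instrument noise and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .binding import UVDirection, UVEvidence
from .errors import DomainError, InsufficientDataError, MissingReferenceError
from .peaks import has_local_maximum, refine_peak
from .types import (
    Band,
    BandAssignment,
    BaseClass,
    DEFAULT_BAND_TABLE,
    FluorescenceSeries,
    FtirSpectrum,
    IonicStrengthRun,
    Probe,
    PROBE_MODES,
    ViscosityRun,
)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the evidence analyses (artifact policy)."""

    displacement: float = 0.10        # fractional intensity drop
    ionic_strength: float = 0.05      # max relative absorbance deviation
    viscosity_change: float = 0.05    # cube-root units over the observed r-range
    uv_shift_nm: float = 2.0
    ftir_base_shift_cm1: float = 2.0
    ftir_backbone_cm1: float = 3.0


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# viscosity
# ---------------------------------------------------------------------------

class ViscosityTrend(Enum):
    UNCHANGED = "unchanged"
    INCREASING = "increasing"
    DECREASING = "decreasing"


@dataclass(frozen=True)
class ViscosityResult:
    r_values: np.ndarray            # [ligand]/[DNA]
    rel_visc_cuberoot: np.ndarray   # (eta/eta0)^(1/3), first entry 1
    slope: float                    # per unit r
    classification: ViscosityTrend
    predicted_change: float         # slope * r-range, cube-root units


def specific_viscosity(flow_time: float, buffer_time: float) -> float:
    """eta = (t - t0)/t0; warns when the DNA solution is not slower than buffer."""
    if buffer_time <= 0:
        raise DomainError("buffer flow time must be positive")
    if flow_time <= buffer_time:
        warnings.warn(
            "flow time <= buffer time: DNA solution should flow slower than buffer",
            stacklevel=2)
    return (flow_time - buffer_time) / buffer_time


def viscosity_analysis(run: ViscosityRun,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS
                       ) -> ViscosityResult:
    """Relative specific viscosity trend vs binding ratio r = [ligand]/[DNA].

    Replicate flow times are averaged first; eta0 comes from the
    zero-ligand point. Classified unchanged when the fitted change over
    the observed r-range stays below the threshold in cube-root units.
    """
    if run.ligand_conc.size < 4:
        raise InsufficientDataError("need >= 4 ligand concentrations")
    if run.ligand_conc[0] != 0.0:
        raise MissingReferenceError("zero-ligand point (eta0) missing")
    t_mean = run.mean_flow_times()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eta = np.array([specific_viscosity(t, run.buffer_flow_time)
                        for t in t_mean])
    if eta[0] <= 0:
        raise DomainError("reference specific viscosity eta0 must be positive")
    rel = np.cbrt(eta / eta[0])
    r = run.ligand_conc / run.dna_conc
    res = stats.linregress(r, rel)
    change = float(res.slope * (r[-1] - r[0]))
    if abs(change) < thresholds.viscosity_change:
        cls = ViscosityTrend.UNCHANGED
    else:
        cls = (ViscosityTrend.INCREASING if res.slope > 0
               else ViscosityTrend.DECREASING)
    return ViscosityResult(r_values=r, rel_visc_cuberoot=rel,
                           slope=float(res.slope), classification=cls,
                           predicted_change=change)


# ---------------------------------------------------------------------------
# competitive displacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementResult:
    probe: Probe
    fractional_change_at_max: float   # (I_maxligand - I0)/I0
    displaced: bool
    monotone_decreasing: bool
    probe_name: str = ""


def displacement_analysis(series: FluorescenceSeries,
                          thresholds: Thresholds = DEFAULT_THRESHOLDS
                          ) -> DisplacementResult:
    """Probe displacement from the intensity drop at the highest ligand load.

    Monotone decrease is called by a sign test on successive differences
    (>= 80% negative).
    """
    i0 = series.intensity[0]
    if i0 <= 0:
        raise DomainError("reference intensity must be positive")
    frac = float((series.intensity[-1] - i0) / i0)
    diffs = np.diff(series.intensity)
    monotone = bool(diffs.size and (diffs < 0).mean() >= 0.8)
    return DisplacementResult(
        probe=series.probe,
        fractional_change_at_max=frac,
        displaced=bool(frac < -thresholds.displacement),
        monotone_decreasing=monotone,
        probe_name=series.probe_name or series.probe.value,
    )


# ---------------------------------------------------------------------------
# ionic strength
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonicStrengthResult:
    max_relative_deviation: float
    electrostatic_component: bool


def ionic_strength_analysis(run: IonicStrengthRun,
                            thresholds: Thresholds = DEFAULT_THRESHOLDS
                            ) -> IonicStrengthResult:
    """Salt dependence of the complex absorbance (zero-NaCl reference)."""
    if run.nacl_conc[0] != 0.0:
        raise MissingReferenceError("zero-NaCl reference point missing")
    a_ref = run.absorbance[0]
    if a_ref <= 0:
        raise DomainError("reference absorbance must be positive")
    dev = float(np.max(np.abs(run.absorbance - a_ref)) / a_ref)
    return IonicStrengthResult(
        max_relative_deviation=dev,
        electrostatic_component=bool(dev > thresholds.ionic_strength),
    )


# ---------------------------------------------------------------------------
# FT-IR band shifts
# ---------------------------------------------------------------------------

#: Half-width (cm^-1) of the search window around each reference position;
#: +-30 keeps the 1711/1665 neighbours (gap 46) from capturing each other.
FTIR_SEARCH_HALFWIDTH = 30.0


@dataclass(frozen=True)
class BandShift:
    band: BandAssignment
    free_position: float    # cm^-1
    bound_position: float   # cm^-1
    shift: float            # bound - free


@dataclass(frozen=True)
class FtirShiftResult:
    per_band: tuple                  # BandShift entries for located bands
    missing_bands: tuple             # Band names not located in a window
    mean_abs_shift_AT: float
    mean_abs_shift_GC: float
    mean_abs_shift_backbone: float
    at_preference: bool
    base_contact: bool
    b_conformation_retained: bool


def ftir_band_shifts(free: FtirSpectrum, bound: FtirSpectrum,
                     assignments: tuple[BandAssignment, ...] = DEFAULT_BAND_TABLE,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS
                     ) -> FtirShiftResult:
    """Per-band peak shifts between free and ligand-bound DNA spectra.

    Each band is located as the local maximum within +-30 cm^-1 of its
    reference position (3-point parabolic refinement). Bands without a
    local maximum are reported missing and excluded from class means.
    """
    f = free.ascending()
    b = bound.ascending()
    shifts: list[BandShift] = []
    missing: list[Band] = []
    for band in assignments:
        lo = band.reference_position - FTIR_SEARCH_HALFWIDTH
        hi = band.reference_position + FTIR_SEARCH_HALFWIDTH
        if not (f.covers(lo, hi) and b.covers(lo, hi)):
            missing.append(band.name)
            warnings.warn(f"band {band.name.value}: spectra do not cover "
                          f"[{lo}, {hi}] cm^-1", stacklevel=2)
            continue
        ok_f = has_local_maximum(f.wavenumbers, f.absorbance, lo, hi)
        ok_b = has_local_maximum(b.wavenumbers, b.absorbance, lo, hi)
        if not (ok_f and ok_b):
            missing.append(band.name)
            warnings.warn(f"band {band.name.value}: no local maximum within "
                          f"+-{FTIR_SEARCH_HALFWIDTH:.0f} cm^-1 of "
                          f"{band.reference_position:.0f}", stacklevel=2)
            continue
        pos_f, _ = refine_peak(f.wavenumbers, f.absorbance, lo, hi)
        pos_b, _ = refine_peak(b.wavenumbers, b.absorbance, lo, hi)
        shifts.append(BandShift(band, pos_f, pos_b, pos_b - pos_f))

    def class_mean(cls: BaseClass) -> float:
        vals = [abs(s.shift) for s in shifts if s.band.base_class is cls]
        return float(np.mean(vals)) if vals else float("nan")

    m_at = class_mean(BaseClass.AT)
    m_gc = class_mean(BaseClass.GC)
    m_bb = class_mean(BaseClass.BACKBONE)
    base_shifts = [abs(s.shift) for s in shifts
                   if s.band.base_class is not BaseClass.BACKBONE]
    return FtirShiftResult(
        per_band=tuple(shifts),
        missing_bands=tuple(missing),
        mean_abs_shift_AT=m_at,
        mean_abs_shift_GC=m_gc,
        mean_abs_shift_backbone=m_bb,
        at_preference=bool(np.isfinite(m_at) and np.isfinite(m_gc)
                           and m_at > m_gc),
        base_contact=bool(base_shifts
                          and max(base_shifts) >= thresholds.ftir_base_shift_cm1),
        b_conformation_retained=bool(not np.isfinite(m_bb)
                                     or m_bb < thresholds.ftir_backbone_cm1),
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class BindingMode(Enum):
    INTERCALATION = "intercalation"
    MINOR_GROOVE = "minor_groove"
    GROOVE = "groove"
    ELECTROSTATIC = "electrostatic"
    MIXED = "mixed"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class EvidenceBundle:
    """Any subset of the five evidence lines; missing items lower
    confidence but never flip a call."""

    uv: UVEvidence | None = None
    viscosity: ViscosityResult | None = None
    displacements: tuple = ()        # DisplacementResult entries
    ionic_strength: IonicStrengthResult | None = None
    ftir: FtirShiftResult | None = None

    def is_empty(self) -> bool:
        return (self.uv is None and self.viscosity is None
                and not self.displacements and self.ionic_strength is None
                and self.ftir is None)


@dataclass(frozen=True)
class ModeVerdict:
    mode: BindingMode
    scores: dict                     # mode name -> supporting fraction
    rationale: tuple                 # human-readable evidence lines


def _probe_result(bundle: EvidenceBundle, mode: str):
    for d in bundle.displacements:
        if PROBE_MODES.get(d.probe) == mode:
            return d
    return None


def classify_binding_mode(bundle: EvidenceBundle,
                          thresholds: Thresholds = DEFAULT_THRESHOLDS
                          ) -> ModeVerdict:
    """Deterministic decision table over the evidence bundle.

    Intercalation: hypochromic UV with a shifted band, OR rising
    viscosity, OR displacement of the intercalator probe. Electrostatic:
    salt-dependent absorbance without intercalation signals. Groove:
    the negative pattern (flat viscosity, intercalator probe retained,
    unshifted UV band, salt invariance) together with at least one
    positive binding signal; refined to minor groove when the
    groove probe is displaced or FT-IR shows AT preference. Conflicting
    strong signals give `mixed`; no signal above threshold gives
    `indeterminate`.
    """
    if bundle.is_empty():
        raise InsufficientDataError("empty evidence bundle")

    rationale: list[str] = []

    # --- intercalation signals -------------------------------------------
    inter_votes: list[bool] = []
    uv = bundle.uv
    if uv is not None:
        hit = uv.direction is UVDirection.HYPOCHROMIC and uv.shifted
        inter_votes.append(hit)
        if hit:
            rationale.append(
                f"UV: hypochromism with {uv.peak_shift:+.1f} nm band shift "
                "(intercalation signature)")
    visc = bundle.viscosity
    if visc is not None:
        hit = visc.classification is ViscosityTrend.INCREASING
        inter_votes.append(hit)
        if hit:
            rationale.append(
                f"viscosity: (eta/eta0)^(1/3) rises by {visc.predicted_change:.3f} "
                "over the titration (helix lengthening)")
    eb = _probe_result(bundle, "intercalation")
    if eb is not None:
        inter_votes.append(eb.displaced)
        if eb.displaced:
            rationale.append(
                f"{eb.probe_name}: intercalator probe displaced "
                f"({eb.fractional_change_at_max:+.0%} intensity)")

    intercalation = any(inter_votes)

    # --- electrostatic signal --------------------------------------------
    ionic = bundle.ionic_strength
    electrostatic = ionic is not None and ionic.electrostatic_component
    if electrostatic:
        rationale.append(
            f"ionic strength: absorbance deviates {ionic.max_relative_deviation:.0%} "
            "with added NaCl (electrostatic component)")

    # --- groove pattern ---------------------------------------------------
    groove_votes: list[bool] = []
    if visc is not None:
        groove_votes.append(visc.classification is ViscosityTrend.UNCHANGED)
    if eb is not None:
        groove_votes.append(not eb.displaced)
    if uv is not None:
        groove_votes.append(not uv.shifted)
    if ionic is not None:
        groove_votes.append(not ionic.electrostatic_component)
    groove_pattern = bool(groove_votes) and all(groove_votes)

    rb = _probe_result(bundle, "minor_groove")
    minor_refined = bool(
        (rb is not None and rb.displaced)
        or (bundle.ftir is not None and bundle.ftir.at_preference))

    # positive evidence that binding happens at all
    binding_signal = bool(
        (uv is not None and uv.direction is not UVDirection.NONE)
        or (rb is not None and rb.displaced)
        or (bundle.ftir is not None and bundle.ftir.base_contact)
        or intercalation)

    if groove_pattern and binding_signal and not intercalation:
        if visc is not None and visc.classification is ViscosityTrend.UNCHANGED:
            rationale.append("viscosity: flat (eta/eta0)^(1/3) excludes intercalation")
        if eb is not None and not eb.displaced:
            rationale.append(f"{eb.probe_name}: intercalator probe retained")
        if uv is not None and not uv.shifted:
            rationale.append(
                f"UV: {uv.direction.value} change with band position unchanged "
                f"({uv.peak_shift:+.1f} nm)")
        if ionic is not None and not ionic.electrostatic_component:
            rationale.append(
                f"ionic strength: absorbance constant within "
                f"{ionic.max_relative_deviation:.1%} (no electrostatic binding)")
        if rb is not None and rb.displaced:
            rationale.append(
                f"{rb.probe_name}: minor-groove probe displaced "
                f"({rb.fractional_change_at_max:+.0%} intensity)")
        if bundle.ftir is not None and bundle.ftir.at_preference:
            rationale.append(
                "FT-IR: AT bands shift more than GC bands (AT-rich minor groove)")
        if bundle.ftir is not None and bundle.ftir.b_conformation_retained:
            rationale.append("FT-IR: phosphate bands unshifted (B-conformation retained)")

    # --- scores -----------------------------------------------------------
    n_inter = max(len(inter_votes), 1)
    scores = {
        BindingMode.INTERCALATION.value: sum(inter_votes) / n_inter,
        BindingMode.MINOR_GROOVE.value:
            ((sum(groove_votes) / len(groove_votes)) if groove_votes else 0.0)
            * (1.0 if minor_refined else 0.5)
            * (1.0 if binding_signal else 0.0),
        BindingMode.ELECTROSTATIC.value: 1.0 if electrostatic else 0.0,
    }

    # --- decision ---------------------------------------------------------
    # A strong groove conflict is the full negative pattern or a displaced
    # groove probe; FT-IR AT preference alone only refines a groove call.
    groove_strong = ((groove_pattern and binding_signal)
                     or (rb is not None and rb.displaced))
    if intercalation and (electrostatic or groove_strong):
        mode = BindingMode.MIXED
        rationale.append("conflicting strong signals across evidence lines")
    elif intercalation:
        mode = BindingMode.INTERCALATION
    elif electrostatic:
        mode = BindingMode.ELECTROSTATIC
    elif groove_pattern and binding_signal:
        mode = BindingMode.MINOR_GROOVE if minor_refined else BindingMode.GROOVE
    else:
        mode = BindingMode.INDETERMINATE
        rationale.append("no evidence line above threshold")
    return ModeVerdict(mode=mode, scores=scores, rationale=tuple(rationale))
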