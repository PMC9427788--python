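"""Domain types for drug/DNA binding experiments.

All concentrations are mol/L, temperatures kelvin, path lengths cm,
wavelengths nm and wavenumbers cm^-1. Each dataclass validates its
invariants on construction so that downstream analyses can assume
well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DomainError, InsufficientDataError


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


def _require_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if np.any(np.diff(arr) <= 0):
        raise DomainError(f"{name} must be strictly increasing (no duplicates)")


@dataclass(frozen=True)
class AbsorbanceTitration:
    """One UV-Vis titration: fixed DNA concentration, varied ligand, one T.

    The first point may be at zero ligand concentration; its absorbance is
    the reference A0 for the Benesi-Hildebrand transform.
    """

    temperature: float            # K
    dna_conc: float               # mol/L (per nucleotide)
    wavelength: float             # nm
    pathlength: float             # cm
    ligand_conc: np.ndarray       # mol/L, strictly increasing
    absorbance: np.ndarray        # dimensionless, >= 0
    label: str = ""

    def __post_init__(self):
        if self.temperature <= 0:
            raise DomainError("temperature must be positive (kelvin)")
        if self.dna_conc <= 0:
            raise DomainError("dna_conc must be positive")
        if self.pathlength <= 0:
            raise DomainError("pathlength must be positive")
        conc = _as_float_array(self.ligand_conc, "ligand_conc")
        absv = _as_float_array(self.absorbance, "absorbance")
        if conc.size != absv.size:
            raise DomainError("ligand_conc and absorbance lengths differ")
        if conc.size and conc[0] < 0:
            raise DomainError("ligand_conc values must be non-negative")
        _require_strictly_increasing(conc, "ligand_conc")
        if np.any(absv < 0):
            raise DomainError("absorbance values must be >= 0")
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "absorbance", absv)

    @property
    def has_reference(self) -> bool:
        return self.ligand_conc.size > 0 and self.ligand_conc[0] == 0.0

    @property
    def a0(self) -> float:
        """Absorbance of DNA alone (zero-ligand reference)."""
        if not self.has_reference:
            raise DomainError("titration has no zero-ligand reference point")
        return float(self.absorbance[0])

    def require_fit_points(self, minimum: int = 4) -> None:
        n_nonzero = int(np.count_nonzero(self.ligand_conc > 0))
        if n_nonzero < minimum:
            raise InsufficientDataError(
                f"need >= {minimum} nonzero-ligand points for fitting, "
                f"got {n_nonzero}"
            )


class Probe(Enum):
    """Fluorescent probe identity with its reporting semantics."""

    EB = "EB"      # ethidium bromide: intercalation reporter
    RB = "RB"      # rhodamine B: minor-groove reporter (AT preference)
    OTHER = "other"


#: Which binding mode each named probe reports on. Probe semantics are data,
#: not code: new probes can be registered here without touching the classifier.
PROBE_MODES: dict[Probe, str] = {
    Probe.EB: "intercalation",
    Probe.RB: "minor_groove",
}


@dataclass(frozen=True)
class FluorescenceSeries:
    """Competitive-displacement fluorescence series for one probe."""

    probe: Probe
    probe_conc: float             # mol/L
    dna_conc: float               # mol/L
    lambda_ex: float              # nm
    lambda_em: float              # nm
    ligand_conc: np.ndarray       # mol/L, first point must be 0
    intensity: np.ndarray         # arbitrary units, > 0
    probe_name: str = ""

    def __post_init__(self):
        conc = _as_float_array(self.ligand_conc, "ligand_conc")
        inten = _as_float_array(self.intensity, "intensity")
        if conc.size != inten.size:
            raise DomainError("ligand_conc and intensity lengths differ")
        if conc.size == 0 or conc[0] != 0.0:
            raise DomainError("first point must be the zero-ligand reference")
        _require_strictly_increasing(conc, "ligand_conc")
        if np.any(inten <= 0):
            raise DomainError("intensities must be positive")
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class ViscosityRun:
    """Capillary-viscometer flow times vs ligand concentration.

    ``flow_times`` holds one list of replicate times (s) per ligand
    concentration; replicates are averaged before computing the specific
    viscosity (t - t0)/t0.
    """

    buffer_flow_time: float       # s, t0
    dna_conc: float               # mol/L
    ligand_conc: np.ndarray       # mol/L, strictly increasing
    flow_times: tuple             # tuple of tuples of s, >=1 replicate each

    def __post_init__(self):
        if self.buffer_flow_time <= 0:
            raise DomainError("buffer_flow_time must be positive")
        if self.dna_conc <= 0:
            raise DomainError("dna_conc must be positive")
        conc = _as_float_array(self.ligand_conc, "ligand_conc")
        _require_strictly_increasing(conc, "ligand_conc")
        times = tuple(tuple(float(t) for t in reps) for reps in self.flow_times)
        if len(times) != conc.size:
            raise DomainError("one replicate list per ligand concentration required")
        for reps in times:
            if len(reps) < 1:
                raise DomainError("each point needs >= 1 flow-time replicate")
            if any(not np.isfinite(t) or t <= 0 for t in reps):
                raise DomainError("flow times must be positive and finite")
        object.__setattr__(self, "ligand_conc", conc)
        object.__setattr__(self, "flow_times", times)

    def mean_flow_times(self) -> np.ndarray:
        return np.array([float(np.mean(reps)) for reps in self.flow_times])


@dataclass(frozen=True)
class IonicStrengthRun:
    """Absorbance of the drug-DNA complex at increasing NaCl concentration."""

    ligand_conc: float            # mol/L
    dna_conc: float               # mol/L
    nacl_conc: np.ndarray         # mol/L, non-negative, strictly increasing
    absorbance: np.ndarray

    def __post_init__(self):
        salt = _as_float_array(self.nacl_conc, "nacl_conc")
        absv = _as_float_array(self.absorbance, "absorbance")
        if salt.size != absv.size:
            raise DomainError("nacl_conc and absorbance lengths differ")
        if salt.size < 3:
            raise InsufficientDataError("need >= 3 NaCl levels")
        if salt[0] < 0:
            raise DomainError("nacl_conc values must be non-negative")
        _require_strictly_increasing(salt, "nacl_conc")
        object.__setattr__(self, "nacl_conc", salt)
        object.__setattr__(self, "absorbance", absv)


@dataclass(frozen=True)
class FtirSpectrum:
    """An FT-IR spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray       # cm^-1
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        wn = _as_float_array(self.wavenumbers, "wavenumbers")
        absv = _as_float_array(self.absorbance, "absorbance")
        if wn.size != absv.size:
            raise DomainError("wavenumbers and absorbance lengths differ")
        if wn.size < 3:
            raise InsufficientDataError("spectrum needs >= 3 points")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DomainError("wavenumber grid must be strictly monotone")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", absv)

    def ascending(self) -> "FtirSpectrum":
        """Return a copy with the grid in increasing wavenumber order."""
        if self.wavenumbers[0] < self.wavenumbers[-1]:
            return self
        return FtirSpectrum(self.wavenumbers[::-1], self.absorbance[::-1],
                            self.label)

    def covers(self, lo: float, hi: float) -> bool:
        wn = self.wavenumbers
        return min(wn[0], wn[-1]) <= lo and max(wn[0], wn[-1]) >= hi


class Band(Enum):
    G = "G"
    T = "T"
    A = "A"
    C = "C"
    PO2_SYM = "PO2_sym"
    PO2_ASYM = "PO2_asym"


class BaseClass(Enum):
    AT = "AT"
    GC = "GC"
    BACKBONE = "backbone"


@dataclass(frozen=True)
class BandAssignment:
    """A named DNA marker band with its reference position and base class."""

    name: Band
    reference_position: float     # cm^-1
    base_class: BaseClass


#: Marker bands of B-form DNA in the 1800-700 cm^-1 region: in-plane carbonyl
#: / ring vibrations of the four bases and the two phosphate stretches.
DEFAULT_BAND_TABLE: tuple[BandAssignment, ...] = (
    BandAssignment(Band.G, 1711.0, BaseClass.GC),
    BandAssignment(Band.T, 1665.0, BaseClass.AT),
    BandAssignment(Band.A, 1608.0, BaseClass.AT),
    BandAssignment(Band.C, 1491.0, BaseClass.GC),
    BandAssignment(Band.PO2_SYM, 1225.0, BaseClass.BACKBONE),
    BandAssignment(Band.PO2_ASYM, 1085.0, BaseClass.BACKBONE),
)
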