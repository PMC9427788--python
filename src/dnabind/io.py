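"""CSV readers/writers, sidecar configs, and sample-quality computations.

Fixed CSV dialect: comma separator, '.' decimal point, UTF-8, one header
row, lines starting with '#' are comments. Column headers carry the unit
suffix (`_M`, `_s`, `_nm`, `_K`, `_cm1`) and are validated literally, so a
micromolar table can never silently masquerade as molar. Experiment
metadata (temperature, concentrations, probe, wavelengths) travels in a
YAML sidecar, one per experiment, so a single CSV schema serves every
temperature.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataFormatError,
    DataParseError,
    DomainError,
    InsufficientDataError,
)
from .types import (
    AbsorbanceTitration,
    FluorescenceSeries,
    FtirSpectrum,
    IonicStrengthRun,
    Probe,
    ViscosityRun,
)

#: Extinction coefficient of a single CT-DNA nucleotide at 260 nm.
EPSILON_260_PER_NUCLEOTIDE = 6600.0  # M^-1 cm^-1

#: A260/A280 ratio above which the DNA is considered protein-free.
PURITY_THRESHOLD = 1.8


# ---------------------------------------------------------------------------
# quality computations
# ---------------------------------------------------------------------------

def purity_ratio(a260: float, a280: float) -> tuple[float, bool]:
    """A260/A280 purity index of a DNA preparation.

    Returns ``(ratio, pass_flag)``; the flag is true only for ratios
    strictly above 1.8 (exactly 1.8 fails).
    """
    if a280 <= 0:
        raise DomainError("a280 must be positive")
    ratio = a260 / a280
    return ratio, ratio > PURITY_THRESHOLD


def dna_concentration(a260: float, pathlength: float = 1.0) -> float:
    """Per-nucleotide DNA concentration (mol/L) from Beer-Lambert at 260 nm."""
    if pathlength <= 0:
        raise DomainError("pathlength must be positive")
    if a260 < 0:
        raise DomainError("a260 must be non-negative")
    return a260 / (EPSILON_260_PER_NUCLEOTIDE * pathlength)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def _read_table(path, required_columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    for col in required_columns:
        if col not in df.columns:
            raise DataFormatError(
                f"{path}: missing required column '{col}' "
                f"(found: {list(df.columns)})"
            )
    out = {}
    for col in required_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise DataParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"'{col}', row {bad[0] + 2}"
            )
        if values.isna().any():
            row = int(values.index[values.isna()][0]) + 2
            raise DataParseError(f"{path}: empty cell in column '{col}', row {row}")
        out[col] = values.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _check_no_duplicates(values: np.ndarray, path, column: str) -> None:
    uniq, counts = np.unique(values, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise DomainError(f"{path}: duplicated {column} value {dup!r}")


def read_titration_csv(path, *, temperature: float, dna_conc: float,
                       wavelength: float = 260.0, pathlength: float = 1.0,
                       label: str = "") -> AbsorbanceTitration:
    """Read a `ligand_conc_M, absorbance` table into an AbsorbanceTitration."""
    df = _read_table(path, ("ligand_conc_M", "absorbance"))
    if len(df) < 5:
        raise InsufficientDataError(
            f"{path}: need >= 5 rows (reference + 4 fit points), got {len(df)}"
        )
    _check_no_duplicates(df["ligand_conc_M"].to_numpy(), path, "ligand_conc_M")
    df = df.sort_values("ligand_conc_M", kind="stable")
    return AbsorbanceTitration(
        temperature=temperature, dna_conc=dna_conc, wavelength=wavelength,
        pathlength=pathlength,
        ligand_conc=df["ligand_conc_M"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        label=label,
    )


def write_titration_csv(titration: AbsorbanceTitration, path) -> None:
    _write_csv(path, ("ligand_conc_M", "absorbance"),
               (titration.ligand_conc, titration.absorbance))


def read_fluorescence_csv(path, *, probe, probe_conc: float, dna_conc: float,
                          lambda_ex: float, lambda_em: float,
                          probe_name: str = "") -> FluorescenceSeries:
    df = _read_table(path, ("ligand_conc_M", "intensity"))
    _check_no_duplicates(df["ligand_conc_M"].to_numpy(), path, "ligand_conc_M")
    df = df.sort_values("ligand_conc_M", kind="stable")
    probe = Probe(probe) if not isinstance(probe, Probe) else probe
    return FluorescenceSeries(
        probe=probe, probe_conc=probe_conc, dna_conc=dna_conc,
        lambda_ex=lambda_ex, lambda_em=lambda_em,
        ligand_conc=df["ligand_conc_M"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        probe_name=probe_name,
    )


def write_fluorescence_csv(series: FluorescenceSeries, path) -> None:
    _write_csv(path, ("ligand_conc_M", "intensity"),
               (series.ligand_conc, series.intensity))


def read_viscosity_csv(path, *, buffer_flow_time: float,
                       dna_conc: float) -> ViscosityRun:
    """Read a long-format `ligand_conc_M, flow_time_s` table (replicates as
    repeated rows) into a ViscosityRun."""
    df = _read_table(path, ("ligand_conc_M", "flow_time_s"))
    groups = df.groupby("ligand_conc_M", sort=True)["flow_time_s"]
    conc = np.array(sorted(groups.groups))
    times = tuple(tuple(groups.get_group(c)) for c in conc)
    return ViscosityRun(buffer_flow_time=buffer_flow_time, dna_conc=dna_conc,
                        ligand_conc=conc, flow_times=times)


def write_viscosity_csv(run: ViscosityRun, path) -> None:
    conc, times = [], []
    for c, reps in zip(run.ligand_conc, run.flow_times):
        for t in reps:
            conc.append(c)
            times.append(t)
    _write_csv(path, ("ligand_conc_M", "flow_time_s"),
               (np.array(conc), np.array(times)))


def read_ionic_strength_csv(path, *, ligand_conc: float,
                            dna_conc: float) -> IonicStrengthRun:
    df = _read_table(path, ("nacl_conc_M", "absorbance"))
    _check_no_duplicates(df["nacl_conc_M"].to_numpy(), path, "nacl_conc_M")
    df = df.sort_values("nacl_conc_M", kind="stable")
    return IonicStrengthRun(ligand_conc=ligand_conc, dna_conc=dna_conc,
                            nacl_conc=df["nacl_conc_M"].to_numpy(),
                            absorbance=df["absorbance"].to_numpy())


def write_ionic_strength_csv(run: IonicStrengthRun, path) -> None:
    _write_csv(path, ("nacl_conc_M", "absorbance"),
               (run.nacl_conc, run.absorbance))


def read_ftir_csv(path, *, label: str = "") -> FtirSpectrum:
    df = _read_table(path, ("wavenumber_cm1", "absorbance"))
    return FtirSpectrum(wavenumbers=df["wavenumber_cm1"].to_numpy(),
                        absorbance=df["absorbance"].to_numpy(), label=label)


def write_ftir_csv(spectrum: FtirSpectrum, path) -> None:
    _write_csv(path, ("wavenumber_cm1", "absorbance"),
               (spectrum.wavenumbers, spectrum.absorbance))


def read_uv_csv(path, *, label: str = ""):
    """Read a `wavelength_nm, absorbance` UV-Vis spectrum."""
    from .binding import UVSpectrum

    df = _read_table(path, ("wavelength_nm", "absorbance"))
    df = df.sort_values("wavelength_nm", kind="stable")
    return UVSpectrum(df["wavelength_nm"].to_numpy(),
                      df["absorbance"].to_numpy(), label)


def write_uv_csv(spectrum, path) -> None:
    _write_csv(path, ("wavelength_nm", "absorbance"),
               (spectrum.wavelength, spectrum.absorbance))


def read_kb_series_csv(path) -> list[tuple[float, float]]:
    """Read a `temperature_K, kb_per_M` table into (T, Kb) pairs."""
    df = _read_table(path, ("temperature_K", "kb_per_M"))
    return [(float(t), float(k))
            for t, k in zip(df["temperature_K"], df["kb_per_M"])]


def _write_csv(path, columns: tuple[str, ...], arrays: tuple[np.ndarray, ...]) -> None:
    # 15 significant digits: round-trips IEEE doubles through text
    buf = _io.StringIO()
    buf.write(",".join(columns) + "\n")
    for row in zip(*arrays):
        buf.write(",".join(f"{v:.15g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# sidecar config
# ---------------------------------------------------------------------------

def read_sidecar(path) -> dict:
    """Read a YAML sidecar config (flat key-value metadata for one file)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: sidecar must be a key-value mapping")
    return data


def write_sidecar(metadata: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)
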