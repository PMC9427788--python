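"""Full-study orchestration: evidence -> Kb(T) -> thermodynamics -> verdict.

A `StudyConfig` (YAML) points at any subset of the five evidence CSVs and
at one or more titrations (or a precomputed Kb series) for the
thermodynamic branch. `run_full_analysis` executes every stage that has
inputs, collects per-stage errors without aborting the rest, and renders
the report both as full-precision JSON and as a human-readable text
summary (Kb to 3 significant figures, Gibbs energies to 2 decimals,
mirroring how such tables are usually printed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import __version__
from .binding import BindingFit, UVEvidence, fit_titration, uv_evidence
from .errors import DnabindError
from .evidence import (
    DEFAULT_THRESHOLDS,
    EvidenceBundle,
    ModeVerdict,
    Thresholds,
    classify_binding_mode,
    displacement_analysis,
    ftir_band_shifts,
    ionic_strength_analysis,
    viscosity_analysis,
)
from . import io as dio
from .thermo import (
    ForceVerdict,
    KbSeries,
    ThermoParams,
    classify_forces,
    vant_hoff_fit,
)


@dataclass
class StudyConfig:
    """Validated study configuration (paths resolved against its directory)."""

    titrations: list = field(default_factory=list)   # dicts with csv + metadata
    kb_series_csv: str | None = None
    uv_spectra: dict | None = None                   # free_csv, bound_csv
    fluorescence: list = field(default_factory=list)
    viscosity: dict | None = None
    ionic_strength: dict | None = None
    ftir: dict | None = None
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = dio.read_sidecar(path)
        thr = DEFAULT_THRESHOLDS
        if "thresholds" in raw:
            thr = dataclasses.replace(DEFAULT_THRESHOLDS, **raw["thresholds"])
        cfg = cls(
            titrations=raw.get("titrations", []) or [],
            kb_series_csv=raw.get("kb_series_csv"),
            uv_spectra=raw.get("uv_spectra"),
            fluorescence=raw.get("fluorescence", []) or [],
            viscosity=raw.get("viscosity"),
            ionic_strength=raw.get("ionic_strength"),
            ftir=raw.get("ftir"),
            thresholds=thr,
            base_dir=Path(path).resolve().parent,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (not self.titrations and self.kb_series_csv is None
                and self.uv_spectra is None and not self.fluorescence
                and self.viscosity is None and self.ionic_strength is None
                and self.ftir is None):
            raise DnabindError(
                "empty study config: provide at least one titration, a Kb "
                "series, or one evidence dataset")

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


@dataclass
class StageError:
    stage: str
    input_file: str
    message: str


@dataclass
class StudyReport:
    fits: list                       # BindingFit per temperature
    thermo: ThermoParams | None
    force: ForceVerdict | None
    bundle: EvidenceBundle
    verdict: ModeVerdict | None
    provenance: dict
    errors: list

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return _plain({
            "binding_fits": self.fits,
            "thermodynamics": self.thermo,
            "force_verdict": self.force,
            "evidence": self.bundle,
            "mode_verdict": self.verdict,
            "provenance": self.provenance,
            "errors": self.errors,
        })

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=True, **kwargs)

    def to_text(self) -> str:
        lines = ["Drug-DNA binding study report", "=" * 31, ""]
        if self.fits:
            lines.append("Benesi-Hildebrand fits")
            lines.append(f"  {'T (K)':>6} {'Kb (M^-1)':>12} {'r':>8} "
                         f"{'S.D':>8} {'dG (kJ/mol)':>12}")
            for f in self.fits:
                kb_txt = f"{f.kb:.3g}" if f.kb_valid else f"invalid({f.kb:.3g})"
                dg = f"{f.delta_g:.2f}" if f.kb_valid else "-"
                lines.append(f"  {f.temperature:>6.0f} {kb_txt:>12} "
                             f"{f.pearson_r:>8.4f} {f.residual_sd:>8.3g} {dg:>12}")
            lines.append("")
        if self.thermo is not None:
            t = self.thermo
            lines.append("Van't Hoff analysis")
            lines.append(f"  dH = {t.delta_h:.2f} kJ/mol, "
                         f"dS = {t.delta_s:.2f} J/mol/K, r = {t.fit_r:.4f}")
            lines.append(f"  {'T (K)':>6} {'dG(-RTlnK)':>12} {'dG(dH-TdS)':>12}")
            for temp, ga, gb in t.per_temperature:
                lines.append(f"  {temp:>6.0f} {ga:>12.2f} {gb:>12.2f}")
            lines.append("")
        if self.force is not None:
            lines.append(f"Dominant forces: {self.force.label.value}")
            lines.append(f"  {self.force.rationale}")
            lines.append("")
        if self.verdict is not None:
            lines.append(f"Binding mode: {self.verdict.mode.value}")
            for r in self.verdict.rationale:
                lines.append(f"  - {r}")
            lines.append("")
        if self.errors:
            lines.append("Stage errors")
            for e in self.errors:
                lines.append(f"  [{e.stage}] {e.input_file}: {e.message}")
            lines.append("")
        return "\n".join(lines)


def _plain(obj):
    """Recursively convert dataclasses/enums/arrays to JSON-safe objects."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [_plain(x) for x in obj.tolist()]
    if isinstance(obj, np.generic):
        return _plain(obj.item())
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(x) for x in obj]
    return str(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_analysis(config: StudyConfig) -> StudyReport:
    """Execute every stage the config has inputs for; never abort midway."""
    errors: list[StageError] = []
    hashes: dict[str, str] = {}

    def guard(stage, path, fn):
        try:
            return fn()
        except (DnabindError, OSError, ValueError) as exc:
            errors.append(StageError(stage, str(path), str(exc)))
            return None

    # --- thermodynamic branch --------------------------------------------
    fits: list[BindingFit] = []
    for spec in config.titrations:
        path = config.resolve(spec["csv"])

        def _fit(path=path, spec=spec):
            hashes[path.name] = _sha256(path)
            tit = dio.read_titration_csv(
                path, temperature=spec["temperature_K"],
                dna_conc=spec["dna_conc_M"],
                wavelength=spec.get("wavelength_nm", 260.0),
                pathlength=spec.get("pathlength_cm", 1.0),
                label=spec.get("label", ""))
            return fit_titration(tit)

        fit = guard("benesi_hildebrand", path, _fit)
        if fit is not None:
            fits.append(fit)
    fits.sort(key=lambda f: f.temperature)

    series: KbSeries | None = None
    if config.kb_series_csv is not None:
        path = config.resolve(config.kb_series_csv)

        def _series(path=path):
            hashes[path.name] = _sha256(path)
            return KbSeries(entries=tuple(dio.read_kb_series_csv(path)),
                            source=str(path))

        series = guard("kb_series", path, _series)
    elif len([f for f in fits if f.kb_valid]) >= 3:
        series = KbSeries(
            entries=tuple((f.temperature, f.kb) for f in fits if f.kb_valid),
            source="fitted Benesi-Hildebrand constants")

    thermo = force = None
    if series is not None:
        thermo = guard("vant_hoff", series.source, lambda: vant_hoff_fit(series))
        if thermo is not None:
            force = classify_forces(thermo.delta_h, thermo.delta_s)

    # --- evidence branch --------------------------------------------------
    thr = config.thresholds
    uv_ev: UVEvidence | None = None
    if config.uv_spectra is not None:
        fp = config.resolve(config.uv_spectra["free_csv"])
        bp = config.resolve(config.uv_spectra["bound_csv"])

        def _uv():
            hashes[fp.name] = _sha256(fp)
            hashes[bp.name] = _sha256(bp)
            return uv_evidence(dio.read_uv_csv(fp, label="free"),
                               dio.read_uv_csv(bp, label="bound"))

        uv_ev = guard("uv_evidence", fp, _uv)

    displacements = []
    for spec in config.fluorescence:
        path = config.resolve(spec["csv"])

        def _disp(path=path, spec=spec):
            hashes[path.name] = _sha256(path)
            ser = dio.read_fluorescence_csv(
                path, probe=spec["probe"], probe_conc=spec["probe_conc_M"],
                dna_conc=spec["dna_conc_M"],
                lambda_ex=spec.get("lambda_ex_nm", 0.0),
                lambda_em=spec.get("lambda_em_nm", 0.0))
            return displacement_analysis(ser, thr)

        res = guard("displacement", path, _disp)
        if res is not None:
            displacements.append(res)

    visc_res = None
    if config.viscosity is not None:
        path = config.resolve(config.viscosity["csv"])

        def _visc():
            hashes[path.name] = _sha256(path)
            run = dio.read_viscosity_csv(
                path, buffer_flow_time=config.viscosity["buffer_flow_time_s"],
                dna_conc=config.viscosity["dna_conc_M"])
            return viscosity_analysis(run, thr)

        visc_res = guard("viscosity", path, _visc)

    ionic_res = None
    if config.ionic_strength is not None:
        path = config.resolve(config.ionic_strength["csv"])

        def _ionic():
            hashes[path.name] = _sha256(path)
            run = dio.read_ionic_strength_csv(
                path, ligand_conc=config.ionic_strength["ligand_conc_M"],
                dna_conc=config.ionic_strength["dna_conc_M"])
            return ionic_strength_analysis(run, thr)

        ionic_res = guard("ionic_strength", path, _ionic)

    ftir_res = None
    if config.ftir is not None:
        fp = config.resolve(config.ftir["free_csv"])
        bp = config.resolve(config.ftir["bound_csv"])

        def _ftir():
            hashes[fp.name] = _sha256(fp)
            hashes[bp.name] = _sha256(bp)
            return ftir_band_shifts(dio.read_ftir_csv(fp, label="free"),
                                    dio.read_ftir_csv(bp, label="bound"),
                                    thresholds=thr)

        ftir_res = guard("ftir", fp, _ftir)

    bundle = EvidenceBundle(uv=uv_ev, viscosity=visc_res,
                            displacements=tuple(displacements),
                            ionic_strength=ionic_res, ftir=ftir_res)
    verdict = None
    if not bundle.is_empty():
        verdict = guard("classify_binding_mode", "<bundle>",
                        lambda: classify_binding_mode(bundle, thr))

    provenance = {
        "version": __version__,
        "thresholds": dataclasses.asdict(thr),
        "input_sha256": hashes,
    }
    return StudyReport(fits=fits, thermo=thermo, force=force, bundle=bundle,
                       verdict=verdict, provenance=provenance, errors=errors)


def write_report(report: StudyReport, out_dir) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    j = out / "report.json"
    t = out / "report.txt"
    j.write_text(report.to_json() + "\n", encoding="utf-8")
    t.write_text(report.to_text(), encoding="utf-8")
    return j, t
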