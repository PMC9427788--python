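"""Named end-to-end scenarios built from the synthetic generators.

Each scenario bundles every evidence experiment for one physical picture
of the drug-DNA interaction, at default noise levels sitting well below
the classification thresholds:

* ``minor_groove`` — the study-mimicking picture: hyperchromism without a
  band shift, flat viscosity, intercalator probe (EB) retained, groove
  probe (RB) displaced, salt invariance, AT-preferential FT-IR shifts
  with an unshifted backbone;
* ``intercalator`` — hypochromism with a red shift, rising viscosity,
  EB displaced;
* ``electrostatic`` — salt-dependent absorbance, everything else flat;
* ``inert`` — no signal in any channel.

``generate_scenario`` returns the raw datasets plus ground truth;
``analyze_scenario`` runs every evidence analysis and aggregates the
bundle, which is what the recovery tests exercise end to end.
"""

from __future__ import annotations

import numpy as np

from .binding import uv_evidence
from .evidence import (
    DEFAULT_THRESHOLDS,
    EvidenceBundle,
    ModeVerdict,
    Thresholds,
    classify_binding_mode,
    displacement_analysis,
    ionic_strength_analysis,
    viscosity_analysis,
    ftir_band_shifts,
)
from .errors import DomainError
from .simulate import (
    simulate_displacement,
    simulate_ftir,
    simulate_ionic_strength,
    simulate_uv_spectra,
    simulate_viscosity,
)
from .types import Probe

SCENARIOS = ("minor_groove", "intercalator", "electrostatic", "inert")

# Probe equilibrium presets. The EB channel uses the published DNA-EB
# association constant (1.4e6 M^-1) against a weak groove-binding ligand;
# the RB channel shares a small minor-groove site pool with comparable
# effective affinities so a groove binder displaces the probe.
_EB = dict(probe=Probe.EB, probe_conc=2.0e-6, dna_conc=5.7e-5,
           site_conc=5.7e-5 / 4.0, probe_kb=1.4e6)
_RB = dict(probe=Probe.RB, probe_conc=4.0e-6, dna_conc=5.7e-5,
           site_conc=2.0e-6, probe_kb=1.0e5)


def generate_scenario(kind: str, seed: int) -> dict:
    """Raw datasets + ground truth for one named scenario."""
    if kind not in SCENARIOS:
        raise DomainError(f"unknown scenario {kind!r} (choose from {SCENARIOS})")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    # Noise levels are instrument-realistic: 2e-4 AU UV photometric noise,
    # 0.5% flow-time repeatability, 1% absorbance repeatability on the salt
    # series, 1e-3 AU FT-IR noise after scan averaging, ~0.5% fluorescence.
    if kind == "minor_groove":
        uv = simulate_uv_spectra("hyperchromic", shift=0.0,
                                 fractional_change=0.10,
                                 noise_sd=2e-4, seed=int(seeds[0]))
        visc = simulate_viscosity("groove", noise_frac=0.005, seed=int(seeds[1]))
        eb = simulate_displacement(ligand_kb=6.42e3, noise_sd=2.0,
                                   seed=int(seeds[2]), **_EB)
        rb = simulate_displacement(ligand_kb=1.0e5, noise_sd=1.0,
                                   seed=int(seeds[3]), **_RB)
        ionic = simulate_ionic_strength(False, noise_frac=0.01,
                                        seed=int(seeds[4]))
        ftir = simulate_ftir({"A": 5.0, "T": 4.0, "G": 1.0, "C": 0.5,
                              "PO2_sym": 0.3, "PO2_asym": 0.3},
                             noise_sd=0.001, seed=int(seeds[5]))
    elif kind == "intercalator":
        uv = simulate_uv_spectra("hypochromic", shift=+8.0,
                                 fractional_change=0.20,
                                 noise_sd=2e-4, seed=int(seeds[0]))
        visc = simulate_viscosity("intercalator", slope=0.8,
                                  noise_frac=0.005, seed=int(seeds[1]))
        eb = simulate_displacement(ligand_kb=5.0e6, noise_sd=2.0,
                                   seed=int(seeds[2]), **_EB)
        rb = simulate_displacement(ligand_kb=0.0, noise_sd=1.0,
                                   seed=int(seeds[3]), **_RB)
        ionic = simulate_ionic_strength(False, noise_frac=0.01,
                                        seed=int(seeds[4]))
        ftir = simulate_ftir({"A": 2.5, "T": 2.5, "G": 3.5, "C": 3.5,
                              "PO2_sym": 0.5, "PO2_asym": 0.5},
                             noise_sd=0.001, seed=int(seeds[5]))
    elif kind == "electrostatic":
        uv = simulate_uv_spectra("none", shift=0.0, fractional_change=0.0,
                                 noise_sd=2e-4, seed=int(seeds[0]))
        visc = simulate_viscosity("groove", noise_frac=0.005, seed=int(seeds[1]))
        eb = simulate_displacement(ligand_kb=0.0, noise_sd=2.0,
                                   seed=int(seeds[2]), **_EB)
        rb = simulate_displacement(ligand_kb=0.0, noise_sd=1.0,
                                   seed=int(seeds[3]), **_RB)
        ionic = simulate_ionic_strength(True, drop_frac=0.20, noise_frac=0.01,
                                        seed=int(seeds[4]))
        ftir = simulate_ftir({}, noise_sd=0.001, seed=int(seeds[5]))
    else:  # inert
        uv = simulate_uv_spectra("none", shift=0.0, fractional_change=0.0,
                                 noise_sd=2e-4, seed=int(seeds[0]))
        visc = simulate_viscosity("groove", noise_frac=0.005, seed=int(seeds[1]))
        eb = simulate_displacement(ligand_kb=0.0, noise_sd=2.0,
                                   seed=int(seeds[2]), **_EB)
        rb = simulate_displacement(ligand_kb=0.0, noise_sd=1.0,
                                   seed=int(seeds[3]), **_RB)
        ionic = simulate_ionic_strength(False, noise_frac=0.01,
                                        seed=int(seeds[4]))
        ftir = simulate_ftir({}, noise_sd=0.001, seed=int(seeds[5]))

    return {
        "label": kind,
        "uv_free": uv[0], "uv_bound": uv[1], "uv_truth": uv[2],
        "viscosity": visc[0], "viscosity_truth": visc[1],
        "eb": eb[0], "eb_truth": eb[1],
        "rb": rb[0], "rb_truth": rb[1],
        "ionic": ionic[0], "ionic_truth": ionic[1],
        "ftir_free": ftir[0], "ftir_bound": ftir[1], "ftir_truth": ftir[2],
    }


def write_paper_like_study(out_dir, seed: int) -> "Path":
    """Write a complete synthetic study to disk and return its config path.

    Produces one titration CSV per temperature (binding constants taken
    from the published palbociclib/CT-DNA series, instrument-level
    absorbance noise), the five evidence CSVs of the minor-groove
    scenario, a ground-truth JSON, and a `study.yaml` ready for
    ``run_full_analysis`` / ``dnabind report``.
    """
    import json
    from pathlib import Path

    from . import io as dio
    from .datasets import PALBOCICLIB_CTDNA_KB, PALBOCICLIB_STUDY_DNA_CONC
    from .report import _plain
    from .simulate import SimulationSpec, simulate_titration

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    titration_entries = []
    truth: dict = {"titrations": []}
    for t_k, kb in PALBOCICLIB_CTDNA_KB.entries:
        spec = SimulationSpec(kb=kb, temperature=t_k,
                              dna_conc=PALBOCICLIB_STUDY_DNA_CONC,
                              seed=int(rng.integers(0, 2**31 - 1)))
        tit, tr = simulate_titration(spec)
        name = f"titration_{int(t_k)}K.csv"
        dio.write_titration_csv(tit, out / name)
        titration_entries.append({"csv": name, "temperature_K": float(t_k),
                                  "dna_conc_M": PALBOCICLIB_STUDY_DNA_CONC})
        truth["titrations"].append(_plain(tr))

    data = generate_scenario("minor_groove", int(rng.integers(0, 2**31 - 1)))
    dio.write_uv_csv(data["uv_free"], out / "uv_free.csv")
    dio.write_uv_csv(data["uv_bound"], out / "uv_bound.csv")
    dio.write_viscosity_csv(data["viscosity"], out / "viscosity.csv")
    dio.write_fluorescence_csv(data["eb"], out / "displacement_eb.csv")
    dio.write_fluorescence_csv(data["rb"], out / "displacement_rb.csv")
    dio.write_ionic_strength_csv(data["ionic"], out / "ionic_strength.csv")
    dio.write_ftir_csv(data["ftir_free"], out / "ftir_free.csv")
    dio.write_ftir_csv(data["ftir_bound"], out / "ftir_bound.csv")
    for key in ("viscosity_truth", "eb_truth", "rb_truth", "ionic_truth",
                "ftir_truth", "uv_truth"):
        truth[key] = _plain(data[key])
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2) + "\n", encoding="utf-8")

    config = {
        "titrations": titration_entries,
        "uv_spectra": {"free_csv": "uv_free.csv", "bound_csv": "uv_bound.csv"},
        "fluorescence": [
            {"csv": "displacement_eb.csv", "probe": "EB",
             "probe_conc_M": _EB["probe_conc"], "dna_conc_M": _EB["dna_conc"],
             "lambda_ex_nm": 525.0, "lambda_em_nm": 574.0},
            {"csv": "displacement_rb.csv", "probe": "RB",
             "probe_conc_M": _RB["probe_conc"], "dna_conc_M": _RB["dna_conc"],
             "lambda_ex_nm": 465.0, "lambda_em_nm": 576.0},
        ],
        "viscosity": {"csv": "viscosity.csv", "buffer_flow_time_s": 100.0,
                      "dna_conc_M": float(data["viscosity"].dna_conc)},
        "ionic_strength": {"csv": "ionic_strength.csv",
                           "ligand_conc_M": 2.0e-5,
                           "dna_conc_M": PALBOCICLIB_STUDY_DNA_CONC},
        "ftir": {"free_csv": "ftir_free.csv", "bound_csv": "ftir_bound.csv"},
    }
    cfg_path = out / "study.yaml"
    dio.write_sidecar(config, cfg_path)
    return cfg_path


def analyze_scenario(data: dict,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS
                     ) -> tuple[EvidenceBundle, ModeVerdict]:
    """Run every evidence analysis on one scenario's datasets and classify."""
    bundle = EvidenceBundle(
        uv=uv_evidence(data["uv_free"], data["uv_bound"]),
        viscosity=viscosity_analysis(data["viscosity"], thresholds),
        displacements=(displacement_analysis(data["eb"], thresholds),
                       displacement_analysis(data["rb"], thresholds)),
        ionic_strength=ionic_strength_analysis(data["ionic"], thresholds),
        ftir=ftir_band_shifts(data["ftir_free"], data["ftir_bound"],
                              thresholds=thresholds),
    )
    return bundle, classify_binding_mode(bundle, thresholds)
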