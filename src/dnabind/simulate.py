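"""Synthetic-data generators with known ground truth.

Every analysis stage has a generator here producing its input type from
explicit physical parameters, so recovery and classification can be
tested offline. Defaults mirror the study design this package targets:
CT-DNA at 8.25e-5 M (per nucleotide), ligand titrated 0-2.5e-5 M in nine
steps, temperatures {298, 303, 308, 313} K, 1 cm path. Noise is additive
Gaussian on absorbance/intensity and multiplicative lognormal on binding
constants; each stochastic generator takes a mandatory seed and uses its
own `numpy.random.Generator` (no global state). Ground truth is returned
alongside every dataset so tests never re-derive it from the code under
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .constants import GAS_CONSTANT
from .errors import ConvergenceError, DomainError
from .thermo import KbSeries
from .types import (
    AbsorbanceTitration,
    Band,
    BandAssignment,
    DEFAULT_BAND_TABLE,
    FluorescenceSeries,
    FtirSpectrum,
    IonicStrengthRun,
    Probe,
    ViscosityRun,
)

# Study-design defaults
DEFAULT_DNA_CONC = 8.25e-5                     # mol/L per nucleotide
DEFAULT_LIGAND_CONCS = tuple(np.linspace(0.0, 2.5e-5, 9))
DEFAULT_TEMPERATURES = (298.0, 303.0, 308.0, 313.0)
DEFAULT_EPS_DNA = 6600.0                       # M^-1 cm^-1 per nucleotide
DEFAULT_EPS_COMPLEX = 9900.0                   # gives ~7% hyperchromism in-range
DEFAULT_NOISE_SD = 2e-4                        # AU, bench-instrument photometric noise


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters for the titration generator."""

    kb: float = 6.42e3                         # M^-1
    dna_conc: float = DEFAULT_DNA_CONC
    ligand_concs: tuple = DEFAULT_LIGAND_CONCS
    eps_dna: float = DEFAULT_EPS_DNA
    eps_complex: float = DEFAULT_EPS_COMPLEX
    pathlength: float = 1.0
    temperature: float = 298.0
    noise_sd: float = DEFAULT_NOISE_SD         # AU, additive Gaussian
    seed: int | None = None
    equilibrium_model: str = "excess_ligand"   # or "exact"

    def __post_init__(self):
        if self.eps_complex == self.eps_dna:
            raise DomainError("eps_complex must differ from eps_dna (no signal)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise DomainError("seed is mandatory for stochastic output")
        if self.equilibrium_model not in ("excess_ligand", "exact"):
            raise DomainError(f"unknown equilibrium model {self.equilibrium_model!r}")


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_kb_series(delta_h: float, delta_s: float,
                       temperatures=DEFAULT_TEMPERATURES,
                       *, noise_sigma: float = 0.0, seed: int | None = None
                       ) -> KbSeries:
    """Kb(T) = exp(-dH*1000/(R*T) + dS/R); dH in kJ/mol, dS in J/mol/K.

    Optional multiplicative lognormal noise (sigma on ln Kb) emulates
    estimate-to-estimate scatter.
    """
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise DomainError("temperatures must be positive")
    ln_kb = -delta_h * 1000.0 / (GAS_CONSTANT * temps) + delta_s / GAS_CONSTANT
    if noise_sigma > 0:
        if seed is None:
            raise DomainError("seed is mandatory for noisy Kb series")
        ln_kb = ln_kb + _rng(seed).normal(0.0, noise_sigma, temps.size)
    return KbSeries(entries=tuple(zip(temps, np.exp(ln_kb))),
                    source="synthetic van't Hoff series")


def bound_fraction(kb: float, ligand_conc, dna_conc: float,
                   model: str = "excess_ligand") -> np.ndarray:
    """Fraction of DNA complexed at each total ligand concentration.

    `excess_ligand` treats free ligand as total ligand, f = KbC/(1+KbC);
    `exact` solves the 1:1 mass-action quadratic
    Kb*(D - x)*(L - x) = x for the complex concentration x.
    """
    c = np.asarray(ligand_conc, dtype=float)
    if model == "excess_ligand":
        return kb * c / (1.0 + kb * c)
    if model != "exact":
        raise DomainError(f"unknown equilibrium model {model!r}")
    d = dna_conc
    # x^2 - (D + L + 1/Kb) x + D*L = 0, take the root in [0, min(D, L)]
    b = d + c + 1.0 / kb
    disc = b * b - 4.0 * d * c
    assert np.all(disc >= 0), "mass-action discriminant negative"
    x = (b - np.sqrt(disc)) / 2.0
    return x / d


def simulate_titration(spec: SimulationSpec
                       ) -> tuple[AbsorbanceTitration, dict]:
    """Generate one absorbance titration plus its ground-truth record."""
    c = np.asarray(spec.ligand_concs, dtype=float)
    f = bound_fraction(spec.kb, c, spec.dna_conc, spec.equilibrium_model)
    a = ((spec.eps_dna * (1.0 - f) + spec.eps_complex * f)
         * spec.dna_conc * spec.pathlength)
    if spec.noise_sd > 0:
        a = a + _rng(spec.seed).normal(0.0, spec.noise_sd, c.size)
    a = np.maximum(a, 0.0)
    titration = AbsorbanceTitration(
        temperature=spec.temperature, dna_conc=spec.dna_conc,
        wavelength=260.0, pathlength=spec.pathlength,
        ligand_conc=c, absorbance=a,
        label=f"synthetic titration (Kb={spec.kb:.4g} M^-1)",
    )
    truth = {
        "kb": spec.kb,
        "eps_dna": spec.eps_dna,
        "eps_complex": spec.eps_complex,
        "bh_intercept": spec.eps_dna / (spec.eps_complex - spec.eps_dna),
        "bound_fraction": f,
        "equilibrium_model": spec.equilibrium_model,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return titration, truth


def simulate_titration_set(delta_h: float, delta_s: float,
                           temperatures=DEFAULT_TEMPERATURES,
                           spec: SimulationSpec = SimulationSpec(seed=0),
                           *, seed: int | None = None
                           ) -> tuple[list[AbsorbanceTitration], dict]:
    """One titration per temperature with Kb(T) on a van't Hoff line."""
    series = simulate_kb_series(delta_h, delta_s, temperatures)
    out, truths = [], []
    for i, (t, kb) in enumerate(series.entries):
        sub_seed = None if spec.noise_sd == 0 else (seed if seed is not None
                                                    else spec.seed) + i
        s = replace(spec, kb=kb, temperature=t, seed=sub_seed)
        tit, truth = simulate_titration(s)
        out.append(tit)
        truths.append(truth)
    return out, {"delta_h": delta_h, "delta_s": delta_s,
                 "per_temperature": truths}


# ---------------------------------------------------------------------------
# competitive displacement
# ---------------------------------------------------------------------------

def competitive_bound_fractions(probe_kb: float, ligand_kb: float,
                                probe_conc: float, ligand_conc: float,
                                site_conc: float, *, tol: float = 1e-12
                                ) -> tuple[float, float, float]:
    """Equilibrium of probe and ligand competing for one site pool.

    Solves S + P <-> PS (Kp), S + L <-> LS (Kl) with mass conservation
    for the free-site concentration by bisection on the monotone site
    balance, to relative tolerance ``tol``. Returns (probe bound
    fraction, ligand bound fraction, free site concentration).
    """
    if probe_kb <= 0:
        raise DomainError("probe_kb must be positive")
    if ligand_kb < 0:
        raise DomainError("ligand_kb must be non-negative")

    def balance(s_free: float) -> float:
        p_free = probe_conc / (1.0 + probe_kb * s_free)
        l_free = (ligand_conc / (1.0 + ligand_kb * s_free)
                  if ligand_kb > 0 else ligand_conc)
        return (s_free * (1.0 + probe_kb * p_free + ligand_kb * l_free)
                - site_conc)

    try:
        s_free = optimize.brentq(balance, 0.0, site_conc,
                                 xtol=tol * site_conc, rtol=8.9e-16,
                                 maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover
        raise ConvergenceError(
            f"site-balance solve failed: {exc}; residual at S_tot = "
            f"{balance(site_conc):.3e}") from exc
    theta_p = probe_kb * s_free / (1.0 + probe_kb * s_free)
    theta_l = ligand_kb * s_free / (1.0 + ligand_kb * s_free)
    return theta_p, theta_l, s_free


def simulate_displacement(probe_kb: float, ligand_kb: float,
                          *, probe: Probe = Probe.RB,
                          probe_conc: float = 4.0e-6,
                          dna_conc: float = 5.7e-5,
                          site_conc: float | None = None,
                          ligand_concs=tuple(np.linspace(0.0, 2.0e-5, 9)),
                          baseline: float = 50.0, gain: float = 2.0e8,
                          noise_sd: float = 0.0, seed: int | None = None
                          ) -> tuple[FluorescenceSeries, dict]:
    """Competitive-displacement fluorescence series on a single site pool.

    Intensity = baseline + gain * [bound probe] + Gaussian noise. With
    ``ligand_kb`` far below ``probe_kb`` the probe is retained (the
    ethidium-bromide-like outcome); comparable constants displace it
    (the rhodamine-B-like outcome).
    """
    if noise_sd > 0 and seed is None:
        raise DomainError("seed is mandatory for noisy output")
    if site_conc is None:
        site_conc = dna_conc / 4.0  # one shared site per ~2 base pairs
    c = np.asarray(ligand_concs, dtype=float)
    bound = np.empty(c.size)
    residuals = np.empty(c.size)
    for i, lc in enumerate(c):
        theta_p, theta_l, s_free = competitive_bound_fractions(
            probe_kb, ligand_kb, probe_conc, float(lc), site_conc)
        p_free = probe_conc / (1.0 + probe_kb * s_free)
        bound[i] = probe_kb * p_free * s_free
        # mass-action residual of the reconstructed equilibrium
        l_free = (float(lc) / (1.0 + ligand_kb * s_free)
                  if ligand_kb > 0 else float(lc))
        residuals[i] = abs(s_free + probe_kb * p_free * s_free
                           + ligand_kb * l_free * s_free - site_conc)
    intensity = baseline + gain * bound
    if noise_sd > 0:
        intensity = intensity + _rng(seed).normal(0.0, noise_sd, c.size)
    series = FluorescenceSeries(
        probe=probe, probe_conc=probe_conc, dna_conc=dna_conc,
        lambda_ex=465.0 if probe is Probe.RB else 525.0,
        lambda_em=576.0 if probe is Probe.RB else 574.0,
        ligand_conc=c, intensity=intensity,
    )
    truth = {"probe_kb": probe_kb, "ligand_kb": ligand_kb,
             "site_conc": site_conc, "probe_bound": bound,
             "mass_action_residuals": residuals, "noise_sd": noise_sd,
             "seed": seed}
    return series, truth


# ---------------------------------------------------------------------------
# viscosity / ionic strength / FT-IR
# ---------------------------------------------------------------------------

def simulate_viscosity(scenario: str, *, slope: float = 0.8,
                       dna_conc: float = DEFAULT_DNA_CONC,
                       ligand_concs=DEFAULT_LIGAND_CONCS,
                       buffer_time: float = 100.0, eta0: float = 0.30,
                       n_replicates: int = 3, noise_frac: float = 0.0,
                       seed: int | None = None) -> tuple[ViscosityRun, dict]:
    """Flow-time series for a groove, intercalator, or nonclassical binder.

    groove: flat (eta/eta0)^(1/3); intercalator: linear rise with the
    given slope per unit binding ratio r; nonclassical (partial)
    intercalation: linear decrease. Multiplicative Gaussian noise of
    fractional SD ``noise_frac`` is applied per replicate flow time.
    """
    if scenario not in ("groove", "intercalator", "nonclassical"):
        raise DomainError(f"unknown viscosity scenario {scenario!r}")
    if noise_frac > 0 and seed is None:
        raise DomainError("seed is mandatory for noisy output")
    c = np.asarray(ligand_concs, dtype=float)
    r = c / dna_conc
    sgn = {"groove": 0.0, "intercalator": +1.0, "nonclassical": -1.0}[scenario]
    cuberoot = 1.0 + sgn * slope * r
    eta = eta0 * cuberoot ** 3
    t_clean = buffer_time * (1.0 + eta)
    rng = _rng(seed)
    reps = []
    for t in t_clean:
        if noise_frac > 0:
            reps.append(tuple(t * (1.0 + rng.normal(0.0, noise_frac))
                              for _ in range(n_replicates)))
        else:
            reps.append((t,) * n_replicates)
    run = ViscosityRun(buffer_flow_time=buffer_time, dna_conc=dna_conc,
                       ligand_conc=c, flow_times=tuple(reps))
    truth = {"scenario": scenario, "slope": sgn * slope, "eta0": eta0,
             "cuberoot_series": cuberoot, "noise_frac": noise_frac,
             "seed": seed}
    return run, truth


def simulate_ionic_strength(electrostatic: bool, *,
                            ligand_conc: float = 2.0e-5,
                            dna_conc: float = DEFAULT_DNA_CONC,
                            nacl_concs=tuple(np.arange(0.0, 0.08, 0.01)),
                            a_ref: float = 0.60, drop_frac: float = 0.20,
                            noise_frac: float = 0.0, seed: int | None = None
                            ) -> tuple[IonicStrengthRun, dict]:
    """NaCl series: flat absorbance, or a linear fall of ``drop_frac`` over
    the salt range when an electrostatic component is present."""
    if noise_frac > 0 and seed is None:
        raise DomainError("seed is mandatory for noisy output")
    salt = np.asarray(nacl_concs, dtype=float)
    a = np.full(salt.size, a_ref)
    if electrostatic:
        a = a_ref * (1.0 - drop_frac * (salt - salt[0]) / (salt[-1] - salt[0]))
    if noise_frac > 0:
        noise = _rng(seed).normal(0.0, noise_frac, salt.size)
        noise[0] = 0.0  # reference measured first, deviations are relative to it
        a = a * (1.0 + noise)
    run = IonicStrengthRun(ligand_conc=ligand_conc, dna_conc=dna_conc,
                           nacl_conc=salt, absorbance=a)
    truth = {"electrostatic": electrostatic, "drop_frac": drop_frac,
             "noise_frac": noise_frac, "seed": seed}
    return run, truth


def simulate_ftir(shifts: dict | None = None, *,
                  grid=(700.0, 1800.0, 1.0), fwhm: float = 25.0,
                  amplitudes: dict | None = None, baseline: float = 0.02,
                  noise_sd: float = 0.0, seed: int | None = None,
                  assignments: tuple[BandAssignment, ...] = DEFAULT_BAND_TABLE
                  ) -> tuple[FtirSpectrum, FtirSpectrum, dict]:
    """Free/bound FT-IR spectrum pair with per-band centre displacements.

    Bands are Gaussians at the assignment reference positions (default
    1 cm^-1 grid over 700-1800 cm^-1, FWHM 25 cm^-1). ``shifts`` maps
    band names (Band or str) to the bound-spectrum displacement in cm^-1.
    """
    if noise_sd > 0 and seed is None:
        raise DomainError("seed is mandatory for noisy output")
    shifts = {Band(k) if not isinstance(k, Band) else k: float(v)
              for k, v in (shifts or {}).items()}
    amplitudes = {Band(k) if not isinstance(k, Band) else k: float(v)
                  for k, v in (amplitudes or {}).items()}
    lo, hi, step = grid
    wn = np.arange(lo, hi + step / 2, step)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def spectrum(shifted: bool) -> np.ndarray:
        y = np.full(wn.size, baseline)
        for band in assignments:
            centre = band.reference_position
            if shifted:
                centre += shifts.get(band.name, 0.0)
            amp = amplitudes.get(band.name, 1.0)
            y = y + amp * np.exp(-0.5 * ((wn - centre) / sigma) ** 2)
        return y

    y_free = spectrum(False)
    y_bound = spectrum(True)
    if noise_sd > 0:
        rng = _rng(seed)
        y_free = y_free + rng.normal(0.0, noise_sd, wn.size)
        y_bound = y_bound + rng.normal(0.0, noise_sd, wn.size)
    free = FtirSpectrum(wn, y_free, label="free DNA (synthetic)")
    bound = FtirSpectrum(wn, y_bound, label="ligand-bound DNA (synthetic)")
    truth = {"shifts": {b.value: shifts.get(b, 0.0)
                        for b in (a.name for a in assignments)},
             "fwhm": fwhm, "noise_sd": noise_sd, "seed": seed}
    return free, bound, truth


def simulate_uv_spectra(direction: str = "hyperchromic", *,
                        peak_free: float = 260.0, shift: float = 0.0,
                        fractional_change: float = 0.10,
                        grid=(220.0, 320.0, 1.0), width: float = 20.0,
                        a_peak: float = 0.545, noise_sd: float = 0.0,
                        seed: int | None = None):
    """Free/bound UV spectrum pair: one Gaussian band with an optional
    bound-state shift and intensity change."""
    from .binding import UVSpectrum  # local import avoids a cycle at import time

    if direction not in ("hyperchromic", "hypochromic", "none"):
        raise DomainError(f"unknown UV direction {direction!r}")
    if noise_sd > 0 and seed is None:
        raise DomainError("seed is mandatory for noisy output")
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    sgn = {"hyperchromic": +1.0, "hypochromic": -1.0, "none": 0.0}[direction]
    scale = 1.0 + sgn * fractional_change

    def band(centre, amp):
        return amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)

    y_free = band(peak_free, a_peak)
    y_bound = band(peak_free + shift, a_peak * scale)
    if noise_sd > 0:
        rng = _rng(seed)
        y_free = y_free + rng.normal(0.0, noise_sd, wl.size)
        y_bound = y_bound + rng.normal(0.0, noise_sd, wl.size)
    truth = {"direction": direction, "shift": shift,
             "fractional_change": sgn * fractional_change}
    return (UVSpectrum(wl, y_free, "free DNA (synthetic)"),
            UVSpectrum(wl, y_bound, "bound DNA (synthetic)"), truth)
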