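# dnabind

Desk analysis of small-molecule/DNA binding studies: binding-constant
estimation from UV–Vis titrations, van't Hoff thermodynamics, and a
multi-evidence binding-mode classifier. Written for the workflow used to
characterize drug–DNA interactions in solution — the worked example
throughout is palbociclib (a CDK4/6 inhibitor) binding calf thymus DNA
(CT-DNA) — and for anyone who wants those analyses reproducible,
validated against synthetic ground truth, and runnable without any
laboratory data.

## What it computes

**Binding constant (Benesi–Hildebrand).** For a 1:1 complex observed
through the DNA chromophore at 260 nm,

    A₀/(A − A₀) = ε_D/(ε_C − ε_D) + ε_D/(ε_C − ε_D) · 1/(K_b·C)

so plotting y = A₀/(A − A₀) against x = 1/C is linear and
K_b = intercept/slope. `dnabind.binding` performs the transform (with
guarded exclusion of no-signal points), the OLS fit with its diagnostics
(Pearson r, residual SD), and ΔG = −RT ln K_b. A direct nonlinear 1:1
isotherm fit is provided as a cross-check.

**Thermodynamics (van't Hoff).** From K_b at several temperatures,
ln K_b = −ΔH°/RT + ΔS°/R gives ΔH° (−R·slope) and ΔS° (R·intercept),
ΔG° by both routes (−RT ln K_b and ΔH° − TΔS°), and a dominant-force
call from the (ΔH°, ΔS°) sign pattern (van der Waals/H-bond,
hydrophobic, electrostatic).

**Binding mode.** Five orthogonal evidence lines — the UV shift rule,
the (η/η₀)^{1/3} viscosity trend vs binding ratio r = [ligand]/[DNA],
competitive displacement of ethidium bromide (intercalation reporter)
and rhodamine B (AT-preferring minor-groove reporter), absorbance
invariance to NaCl, and FT-IR shifts of the G/T/A/C marker bands (1711,
1665, 1608, 1491 cm⁻¹) and phosphate stretches (1225, 1085 cm⁻¹) — feed
a deterministic decision table that returns intercalation, (minor-)
groove, electrostatic, mixed, or indeterminate, with a rationale line
per contributing evidence item.

**Synthetic data.** `dnabind.simulate` generates every input type from
explicit physical parameters (1:1 mass-action equilibria solved exactly
or in the excess-ligand limit, competitive two-species site binding,
Gaussian spectral bands, seeded instrument noise), always returning the
ground truth alongside the dataset.

## Worked example

The analysis scripts replay the palbociclib study end to end on
synthetic data (the original raw spectra are not deposited):

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_fit_binding_constants.py
python analysis/03_thermodynamics.py
python analysis/04_binding_mode.py
```

The thermodynamic step applied to the four published binding constants
(6.42·10³, 6.26·10³, 6.16·10³, 6.01·10³ M⁻¹ at 298–313 K) prints:

```
published constants: dH = -3.32 kJ/mol, dS = 61.74 J/mol/K, r = 0.9966
  T=298 K  dG(-RTlnK)= -21.72  dG(dH-TdS)= -21.72  kJ/mol (routes agree to 0.002)
  T=303 K  dG(-RTlnK)= -22.02  dG(dH-TdS)= -22.03  kJ/mol (routes agree to 0.006)
  T=308 K  dG(-RTlnK)= -22.34  dG(dH-TdS)= -22.34  kJ/mol (routes agree to 0.007)
  T=313 K  dG(-RTlnK)= -22.64  dG(dH-TdS)= -22.65  kJ/mol (routes agree to 0.003)
```

ΔG° < 0 at every temperature: binding is spontaneous, with a small
exothermic enthalpy and a favourable entropy. (The study's own printed
ΔH° = −33.09 kJ/mol is inconsistent with its K_b and ΔG° columns; the
script flags this and reports the refit value — see `docs/methods.md`.)

The mode step aggregates the evidence into:

```
Binding mode: minor_groove
  - viscosity: flat (eta/eta0)^(1/3) excludes intercalation
  - EB: intercalator probe retained
  - UV: hyperchromic change with band position unchanged (+0.2 nm)
  - ionic strength: absorbance constant within 1.6% (no electrostatic binding)
  - RB: minor-groove probe displaced (-38% intensity)
  - FT-IR: AT bands shift more than GC bands (AT-rich minor groove)
  - FT-IR: phosphate bands unshifted (B-conformation retained)
```

i.e. a minor-groove binder: the helix is not lengthened, the
intercalation reporter stays bound, and the AT-biased infrared shifts
point at the AT-rich minor groove.

The same pipeline is scriptable (`dnabind fit-kb`, `dnabind thermo`,
`dnabind mode`, `dnabind simulate`, `dnabind report`) or callable as a
library (`dnabind.report.run_full_analysis`).

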