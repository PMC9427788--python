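# Methods

This note documents the models, the numeric policies, and the design
choices behind `dnabind`, in the package's own words. It states no
empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Benesi–Hildebrand estimation

The titration model assumes a single 1:1 association equilibrium between
the ligand and a DNA "site", observed through the DNA chromophore at a
fixed wavelength: A = [ε_D(1−f) + ε_C f]·c_DNA·ℓ, with f the complexed
fraction. In the excess-ligand limit f = K_b·C/(1+K_b·C), which
linearizes to

    y = A₀/(A − A₀) = a + (a/K_b)·x,  x = 1/C,  a = ε_D/(ε_C − ε_D).

The primary estimator is unweighted OLS on (x, y) because the quoted
fit diagnostics of such studies (Pearson r, residual SD with an n−2
denominator) are properties of exactly that straight line. A nonlinear
1:1 isotherm fit (`fit_isotherm_nonlinear`) is available as a secondary
cross-check and agrees with the linearization to 1e-6 relative on
noise-free data.

Numeric policies:

* points with |A − A₀| < 1e-4 AU are excluded (the ordinate diverges
  below instrument noise); exclusions are reported with reasons, never
  silent;
* a zero slope within machine tolerance raises a no-binding-signal
  error; a non-positive intercept/slope ratio is returned but flagged
  invalid (`kb_valid = False`) rather than silently propagated;
* ΔG° = −RT ln K_b with R = 8.314 J mol⁻¹ K⁻¹. Reports of this analysis
  sometimes print the relation without the minus sign while tabulating
  negative energies; the thermodynamic sign convention is used
  throughout so that K_b > 1 ⇔ ΔG° < 0.

### Conditioning caveat (important)

With c_DNA = 8.25e-5 M, ligand ≤ 2.5e-5 M and K_b ≈ 6.4e3 M⁻¹, the
complex never exceeds ~14% saturation (K_b·C ≤ 0.16). In that regime the
BH intercept is an extrapolation over a ~50-fold x-range, and
K_b = intercept/slope is strongly noise-sensitive: at a realistic
photometric noise of 2e-4 AU the run-to-run spread of K_b is tens of
percent (the test suite's seeded median over 50 replicates is required
only to land within 15% of truth), and occasional replicates yield a
negative — flagged — K_b. Notably, the regression diagnostics in this
regime (r ≈ 0.999, residual SD ≈ 0.4–1.2) look excellent, so a high r
must not be read as a precise K_b. Under the exact (non-excess) 1:1
equilibrium the estimator is additionally biased when the DNA is not
dilute; the bias falls monotonically as c_DNA → 0, which the property
tests assert over a dilution series.

## Van't Hoff analysis

OLS of ln K_b on 1/T gives ΔH° = −R·slope (kJ/mol) and ΔS° = R·intercept
(J mol⁻¹ K⁻¹), assuming both are temperature-independent over the
fitted 15 K window (no ΔCp correction — a deliberate non-goal). ΔG° is
computed by both routes, −RT ln K_b per temperature and ΔH° − TΔS°, and
their agreement is an internal-consistency check: on an exact van't Hoff
line they agree to < 1e-9 kJ/mol. A two-point series is solved exactly
but flagged (`exact_two_point`, r undefined).

Applied to the published palbociclib/CT-DNA constants, the refit gives
ΔH° ≈ −3.3 kJ/mol and ΔS° ≈ 61.7 J mol⁻¹ K⁻¹, and both ΔG° routes
reproduce the published −21.7…−22.6 kJ/mol column. The study's printed
ΔH° = −33.09 kJ/mol cannot be reconciled with its own K_b or ΔG° values
(−33.09 − 298×0.06178 = −51.5 ≠ −21.72) and is most plausibly a
decimal-place error; the package reports its own fit and flags the
discrepancy rather than adopting the printed number.

## Force classification

The (ΔH°, ΔS°) sign rules: both negative → van der Waals and/or
hydrogen bonding; both positive → hydrophobic; ΔS° > 0 with ΔH° ≈ 0 →
electrostatic; ΔS° > 0 with clearly negative ΔH° → hydrophobic plus
hydrogen bonding. "≈ 0" is implemented as |ΔH°| ≤ 4 kJ/mol (roughly
1.5 RT at 298 K), configurable. The rules are heuristics and behave
accordingly near the band edge: the palbociclib refit (ΔH° ≈ −3.3)
falls just inside the ≈0 band and classifies as electrostatic, even
though the salt-invariance experiment argues against electrostatic
binding — a reminder that the force call should be read together with
the evidence bundle, not alone.

## Mode evidence and thresholds

The source experiments are described qualitatively ("practically
constant", "did not almost affect"); all numeric thresholds are
therefore package policy, set at roughly 2–5× typical instrument noise
and configurable through `Thresholds`:

| quantity | default | unit |
|---|---|---|
| probe displacement (intensity drop at max load) | 0.10 | fraction |
| ionic-strength deviation (max rel. to zero-salt) | 0.05 | fraction |
| viscosity change over the observed r-range | 0.05 | (η/η₀)^{1/3} units |
| UV band shift | 2 | nm |
| FT-IR base-band shift significance | 2 | cm⁻¹ |
| FT-IR backbone retention | 3 | cm⁻¹ |

Viscosity replicates are averaged before η = (t−t₀)/t₀; the series is
reported as (η/η₀)^{1/3} against r with an OLS slope, and "unchanged"
means the fitted change across the observed r-range stays below
threshold. Peak positions (UV and FT-IR) are refined by a parabola
through the three samples around the windowed maximum; FT-IR bands are
searched within ±30 cm⁻¹ of their reference positions so the
1711/1665 cm⁻¹ neighbours (46 cm⁻¹ apart) cannot capture each other.
Bands without a local maximum in their window are reported missing,
excluded from class means, and warned about. Probe semantics (EB →
intercalation reporter, RB → minor-groove reporter) are data, not code.

The decision table: intercalation requires hypochromism with a shifted
band, OR rising viscosity, OR displacement of the intercalator probe.
Electrostatic requires salt dependence without intercalation signals.
A groove call requires the full negative pattern (flat viscosity,
retained intercalator probe, unshifted UV band, salt invariance, over
whichever of those are present) plus at least one positive binding
signal, and is refined to minor groove when the groove probe is
displaced or the FT-IR shifts are AT-preferential. Contradictory strong
signals (intercalation vs the full groove pattern or a displaced groove
probe, or intercalation vs salt dependence) give `mixed`; FT-IR AT
preference alone does not veto intercalation, it only refines a groove
call. Missing evidence reduces the score, never flips a verdict; the
classifier is deterministic and order-independent.

## Synthetic generators

The generators emulate the study design: DNA 8.25e-5 M per nucleotide
(ε₂₆₀ = 6600 M⁻¹cm⁻¹, 1 cm path, A₀ ≈ 0.545), ligand 0–2.5e-5 M in nine
steps, temperatures 298–313 K. Defaults chosen once as realistic study
conditions:

* ε_complex = 9900 M⁻¹cm⁻¹ (BH intercept a = 2), giving ~7% in-range
  hyperchromism — a moderate, physically plausible response;
* absorbance noise 2e-4 AU additive Gaussian (bench-spectrophotometer
  photometric noise). At this level the synthetic BH diagnostics
  (r ≈ 0.999, residual SD ≈ 0.4–1.2 on the transformed ordinate) match
  the magnitudes such studies print;
* K_b-series noise is multiplicative lognormal (estimate-error
  structure), titration/intensity noise additive (instrument structure);
* the exact-equilibrium generator solves the 1:1 mass-action quadratic
  and conserves mass to < 1e-12 relative; the competitive-displacement
  generator solves the two-species shared-site equilibrium by bracketed
  root finding to 1e-12 and exposes its mass-action residuals;
* the EB channel uses the published DNA–EB constant (1.4e6 M⁻¹) against
  a weak groove binder (no displacement); the RB channel uses a small
  shared minor-groove site pool with comparable effective affinities
  (1e5/1e5 M⁻¹) so the ligand displaces ~40% of the probe signal. The
  effective site-pool affinities are scenario parameters, not measured
  constants — no displacement intensities are published to calibrate
  against;
* FT-IR bands are Gaussians (FWHM 25 cm⁻¹, 1 cm⁻¹ grid, noise 1e-3 AU);
  UV bands are Gaussians on a 1 nm grid (noise 2e-4 AU); viscosity
  flow-time noise is 0.5% multiplicative; salt-series repeatability 1%.
  These sit at least a factor ~2 below the corresponding thresholds so
  that scenario classification is stable (the multi-point maximum-
  deviation statistic, not the per-point σ, is what must clear the
  threshold).

Every stochastic generator requires a seed and uses its own
`numpy.random.Generator`; identical parameters give byte-identical CSVs.
Ground truth always travels with the dataset.

What the generators do **not** emulate: full spectral band shapes,
baselines and scattering, inner-filter and photobleaching effects,
multi-site or cooperative binding, sequence heterogeneity of CT-DNA.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated models, not robustness to every
real-data artefact.

## Problem sizes

The test suite and analysis scripts run at desk scale by choice: 100
seeded replicates for classification and recovery rates, 500 for the
van't Hoff unbiasedness check, 9-point titrations, 1101-point FT-IR
grids. The whole suite completes in a few seconds.

## Known limitations

* The BH K_b is ill-conditioned in weak-saturation designs (above); a
  design with higher ligand loads or a global multi-wavelength fit would
  condition it better, but both are out of scope.
* The force rules are discrete heuristics with a configurable ≈0 band;
  values near the band edge are genuinely ambiguous.
* FT-IR analysis assumes isolated marker bands; overlapping or shifted
  baselines are not corrected (baseline correction is a non-goal).
* CSV is the only supported format (fixed dialect, unit-suffixed
  headers); instrument-vendor formats are out of scope.
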