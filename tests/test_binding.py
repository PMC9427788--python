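"""Benesi-Hildebrand transform, fit, Gibbs energy, and UV evidence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnabind import errors
from dnabind.binding import (
    BHPoint,
    UVDirection,
    bh_transform,
    fit_benesi_hildebrand,
    fit_isotherm_nonlinear,
    fit_titration,
    gibbs_from_kb,
    uv_evidence,
)
from dnabind.simulate import (
    SimulationSpec,
    simulate_titration,
    simulate_uv_spectra,
)
from dnabind.types import AbsorbanceTitration


def make_titration(concs, absorbances, **kw):
    defaults = dict(temperature=298.0, dna_conc=8.25e-5, wavelength=260.0,
                    pathlength=1.0)
    defaults.update(kw)
    return AbsorbanceTitration(ligand_conc=np.asarray(concs),
                               absorbance=np.asarray(absorbances), **defaults)


class TestBhTransform:
    def test_doubling_point_gives_unit_ordinate(self):
        tit = make_titration([0, 2e-6, 4e-6, 6e-6, 1e-5],
                             [0.5, 0.6, 0.7, 0.8, 1.0])
        points, dropped = bh_transform(tit)
        # last point has A = 2*A0 -> y = A0/A0 = 1
        assert points[-1].inv_ligand_conc == pytest.approx(1e5)
        assert points[-1].y == pytest.approx(1.0)
        assert dropped == []

    def test_flat_point_excluded_with_reason(self):
        tit = make_titration([0, 1e-6, 2e-6, 4e-6, 6e-6, 1e-5],
                             [0.5, 0.50005, 0.6, 0.7, 0.8, 1.0])
        points, dropped = bh_transform(tit)
        assert len(points) == 4
        assert dropped[0][0] == pytest.approx(1e-6)
        assert "no signal change" in dropped[0][1]

    def test_missing_reference_raises(self):
        tit = make_titration([1e-6, 2e-6, 4e-6, 6e-6, 1e-5],
                             [0.5, 0.6, 0.7, 0.8, 1.0])
        with pytest.raises(errors.MissingReferenceError):
            bh_transform(tit)

    def test_algebraic_identity_on_saturation_model(self):
        # A(C) = A0*(1 + (1/a)*KbC/(1+KbC)) with a = 2, Kb = 5000 gives
        # y = a + a/(Kb*C) exactly at every concentration.
        kb, a = 5000.0, 2.0
        concs = np.linspace(0, 2.5e-5, 9)
        a0 = 0.5445
        f = kb * concs / (1 + kb * concs)
        tit = make_titration(concs, a0 * (1 + f / a))
        points, _ = bh_transform(tit)
        for p in points:
            assert p.y == pytest.approx(a + a * p.inv_ligand_conc / kb, rel=1e-9)


class TestFitBenesiHildebrand:
    def test_exact_line_recovers_kb(self):
        x = np.array([4e4, 8e4, 1.6e5, 3.2e5])
        pts = [BHPoint(xi, 2.0 + 2.0 * xi / 5000.0) for xi in x]
        fit = fit_benesi_hildebrand(pts, 298.0)
        assert fit.kb == pytest.approx(5000.0, rel=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert fit.kb_valid

    def test_unit_line(self):
        pts = [BHPoint(x, 1.0 + x) for x in (1.0, 2.0, 3.0, 4.0)]
        fit = fit_benesi_hildebrand(pts, 298.0)
        assert fit.kb == pytest.approx(1.0, rel=1e-12)

    def test_zero_slope_raises(self):
        pts = [BHPoint(x, 2.0) for x in (1.0, 2.0, 3.0)]
        with pytest.raises(errors.NoBindingSignalError):
            fit_benesi_hildebrand(pts, 298.0)

    def test_negative_kb_flagged_not_silent(self):
        pts = [BHPoint(x, 1.0 - 0.2 * x) for x in (1.0, 2.0, 3.0, 4.0)]
        fit = fit_benesi_hildebrand(pts, 298.0)
        assert not fit.kb_valid

    def test_noisy_median_recovery_at_instrument_noise(self):
        # Individual BH estimates scatter widely in this weak-saturation
        # design; the seeded median over 50 runs stays near truth.
        kbs = []
        for seed in range(50):
            tit, _ = simulate_titration(
                SimulationSpec(kb=6.42e3, noise_sd=2e-4, seed=seed))
            kbs.append(fit_titration(tit).kb)
        assert np.median(kbs) == pytest.approx(6.42e3, rel=0.15)


@given(st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=30, deadline=None)
def test_scale_invariance_of_transform_and_fit(k, ):
    spec = SimulationSpec(kb=5000.0, noise_sd=0.0)
    tit, _ = simulate_titration(spec)
    scaled = AbsorbanceTitration(
        temperature=tit.temperature, dna_conc=tit.dna_conc,
        wavelength=tit.wavelength, pathlength=tit.pathlength,
        ligand_conc=tit.ligand_conc, absorbance=k * tit.absorbance)
    f1, f2 = fit_titration(tit), fit_titration(scaled)
    assert f2.kb == pytest.approx(f1.kb, rel=1e-9)
    assert f2.pearson_r == pytest.approx(f1.pearson_r, rel=1e-9)


@pytest.mark.parametrize("kb", [1e2, 1e3, 1e4, 1e5, 1e6, 1e7])
def test_oracle_equivalence_noise_free(kb):
    """Noise-free excess-ligand data return the generator's Kb exactly."""
    tit, _ = simulate_titration(SimulationSpec(kb=kb, noise_sd=0.0))
    fit = fit_titration(tit)
    assert abs(fit.kb - kb) / kb < 1e-9


def test_nonlinear_isotherm_cross_check_agrees():
    tit, _ = simulate_titration(SimulationSpec(kb=6.42e3, noise_sd=0.0))
    bh = fit_titration(tit)
    iso = fit_isotherm_nonlinear(tit)
    assert iso["kb"] == pytest.approx(bh.kb, rel=1e-6)


def test_bh_bias_shrinks_with_dna_dilution():
    """Under exact 1:1 equilibrium the excess-ligand BH estimate is biased;
    the bias must fall monotonically as the DNA concentration drops."""
    errs = []
    for dna in (8.25e-5, 4e-5, 1e-5):
        spec = SimulationSpec(kb=6.42e3, dna_conc=dna, noise_sd=0.0,
                              equilibrium_model="exact")
        tit, _ = simulate_titration(spec)
        errs.append(abs(fit_titration(tit).kb - 6.42e3) / 6.42e3)
    assert errs[0] > errs[1] > errs[2]


class TestGibbsFromKb:
    @pytest.mark.parametrize("kb, t, dg", [
        (6.42e3, 298.0, -21.72),    # published value at 298 K
        (1.0, 310.0, 0.0),
        (6.16e3, 308.0, -22.344),   # published value at 308 K
    ])
    def test_reference_values(self, kb, t, dg):
        assert gibbs_from_kb(kb, t) == pytest.approx(dg, abs=0.01)

    def test_strictly_decreasing_in_kb_and_zero_at_unity(self):
        kbs = np.logspace(-2, 7, 30)
        dgs = [gibbs_from_kb(k, 298.0) for k in kbs]
        assert all(a > b for a, b in zip(dgs, dgs[1:]))
        assert gibbs_from_kb(1.0, 298.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(errors.DomainError):
            gibbs_from_kb(0.0, 298.0)
        with pytest.raises(errors.DomainError):
            gibbs_from_kb(100.0, -1.0)


class TestUvEvidence:
    def test_identical_spectra_no_evidence(self):
        free, _, _ = simulate_uv_spectra("none", fractional_change=0.0)
        ev = uv_evidence(free, free)
        assert ev.direction is UVDirection.NONE
        assert ev.peak_shift == pytest.approx(0.0, abs=1e-9)
        assert not ev.shifted

    def test_pure_scaling_is_hyperchromic_without_shift(self):
        free, _, _ = simulate_uv_spectra("none", fractional_change=0.0)
        from dnabind.binding import UVSpectrum
        bound = UVSpectrum(free.wavelength, 1.2 * free.absorbance)
        ev = uv_evidence(free, bound)
        assert ev.direction is UVDirection.HYPERCHROMIC
        assert ev.peak_shift == pytest.approx(0.0, abs=1e-9)
        assert ev.max_fractional_change == pytest.approx(0.2, rel=1e-9)

    def test_eight_nm_shift_recovered(self):
        free, bound, _ = simulate_uv_spectra("none", shift=8.0,
                                             fractional_change=0.0)
        ev = uv_evidence(free, bound)
        assert ev.peak_shift == pytest.approx(8.0, abs=0.3)
        assert ev.shifted

    def test_grid_mismatch_raises(self):
        free, _, _ = simulate_uv_spectra("none")
        from dnabind.binding import UVSpectrum
        other = UVSpectrum(free.wavelength + 0.25, free.absorbance)
        with pytest.raises(errors.AlignmentError):
            uv_evidence(free, other)
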