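"""Viscosity, displacement, ionic-strength, FT-IR analyses and the
binding-mode decision table."""

import numpy as np
import pytest

from dnabind import errors
from dnabind.binding import UVDirection, UVEvidence, uv_evidence
from dnabind.evidence import (
    BindingMode,
    EvidenceBundle,
    ViscosityTrend,
    classify_binding_mode,
    displacement_analysis,
    ftir_band_shifts,
    ionic_strength_analysis,
    specific_viscosity,
    viscosity_analysis,
)
from dnabind.simulate import (
    simulate_displacement,
    simulate_ftir,
    simulate_ionic_strength,
    simulate_viscosity,
)
from dnabind.types import (
    FluorescenceSeries,
    FtirSpectrum,
    IonicStrengthRun,
    Probe,
    ViscosityRun,
)


class TestSpecificViscosity:
    @pytest.mark.parametrize("t, t0, eta", [
        (100.0, 100.0, 0.0),
        (200.0, 100.0, 1.0),
        (110.0, 100.0, 0.1),
    ])
    def test_arithmetic(self, t, t0, eta):
        if t <= t0:
            with pytest.warns(UserWarning):
                assert specific_viscosity(t, t0) == pytest.approx(eta)
        else:
            assert specific_viscosity(t, t0) == pytest.approx(eta)

    def test_bad_buffer_time(self):
        with pytest.raises(errors.DomainError):
            specific_viscosity(100.0, 0.0)


class TestViscosityAnalysis:
    def test_equal_flow_times_unchanged(self):
        run, _ = simulate_viscosity("groove")
        res = viscosity_analysis(run)
        np.testing.assert_allclose(res.rel_visc_cuberoot, 1.0, atol=1e-12)
        assert res.classification is ViscosityTrend.UNCHANGED
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_intercalator_series_increasing(self):
        run, _ = simulate_viscosity("intercalator", slope=0.8)
        res = viscosity_analysis(run)
        assert res.classification is ViscosityTrend.INCREASING
        assert res.predicted_change > 0.05

    def test_flat_with_noise_below_threshold_unchanged(self):
        run, _ = simulate_viscosity("groove", noise_frac=0.005, seed=7)
        res = viscosity_analysis(run)
        assert res.classification is ViscosityTrend.UNCHANGED

    def test_nonclassical_series_decreasing(self):
        run, _ = simulate_viscosity("nonclassical", slope=0.8)
        assert (viscosity_analysis(run).classification
                is ViscosityTrend.DECREASING)

    def test_missing_zero_ligand_point(self):
        run = ViscosityRun(buffer_flow_time=100.0, dna_conc=8.25e-5,
                           ligand_conc=np.array([1e-6, 2e-6, 3e-6, 4e-6]),
                           flow_times=((130.0,),) * 4)
        with pytest.raises(errors.MissingReferenceError):
            viscosity_analysis(run)

    def test_invariant_to_time_rescaling(self):
        run, _ = simulate_viscosity("intercalator", noise_frac=0.005, seed=3)
        k = 3.7
        scaled = ViscosityRun(
            buffer_flow_time=k * run.buffer_flow_time, dna_conc=run.dna_conc,
            ligand_conc=run.ligand_conc,
            flow_times=tuple(tuple(k * t for t in reps)
                             for reps in run.flow_times))
        r1, r2 = viscosity_analysis(run), viscosity_analysis(scaled)
        np.testing.assert_allclose(r2.rel_visc_cuberoot, r1.rel_visc_cuberoot,
                                   rtol=1e-12)
        assert r2.classification is r1.classification


def _series(intensities, probe=Probe.EB):
    c = np.linspace(0.0, 2e-5, len(intensities))
    return FluorescenceSeries(probe=probe, probe_conc=2e-6, dna_conc=5.7e-5,
                              lambda_ex=525.0, lambda_em=574.0,
                              ligand_conc=c,
                              intensity=np.asarray(intensities, dtype=float))


class TestDisplacementAnalysis:
    def test_constant_intensity_not_displaced(self):
        res = displacement_analysis(_series([100.0] * 6))
        assert res.fractional_change_at_max == pytest.approx(0.0)
        assert not res.displaced

    def test_competitive_ligand_displaces_probe(self):
        series, _ = simulate_displacement(probe_kb=1e5, ligand_kb=1e5,
                                          site_conc=2e-6)
        res = displacement_analysis(series)
        assert res.displaced
        assert res.monotone_decreasing
        assert res.fractional_change_at_max < -0.30

    def test_small_drop_below_threshold(self):
        res = displacement_analysis(_series([100, 99, 98, 97, 96, 95]))
        assert res.fractional_change_at_max == pytest.approx(-0.05)
        assert not res.displaced

    def test_scale_invariance(self):
        s1 = _series([100, 80, 70, 65, 60, 58])
        s2 = _series([1000, 800, 700, 650, 600, 580])
        r1, r2 = displacement_analysis(s1), displacement_analysis(s2)
        assert r1.fractional_change_at_max == pytest.approx(
            r2.fractional_change_at_max, rel=1e-12)
        assert r1.displaced == r2.displaced


class TestIonicStrengthAnalysis:
    def test_constant_absorbance(self):
        run, _ = simulate_ionic_strength(False)
        res = ionic_strength_analysis(run)
        assert res.max_relative_deviation == pytest.approx(0.0)
        assert not res.electrostatic_component

    def test_twenty_percent_drop_flags_electrostatic(self):
        run, _ = simulate_ionic_strength(True, drop_frac=0.20)
        res = ionic_strength_analysis(run)
        assert res.max_relative_deviation == pytest.approx(0.20, abs=0.01)
        assert res.electrostatic_component

    def test_jitter_below_threshold(self):
        run, _ = simulate_ionic_strength(False, noise_frac=0.01, seed=3)
        assert not ionic_strength_analysis(run).electrostatic_component

    def test_missing_zero_salt_reference(self):
        run = IonicStrengthRun(ligand_conc=2e-5, dna_conc=8.25e-5,
                               nacl_conc=np.array([0.01, 0.02, 0.03]),
                               absorbance=np.array([0.6, 0.6, 0.6]))
        with pytest.raises(errors.MissingReferenceError):
            ionic_strength_analysis(run)

    def test_scale_invariance(self):
        run, _ = simulate_ionic_strength(True, drop_frac=0.1)
        scaled = IonicStrengthRun(ligand_conc=run.ligand_conc,
                                  dna_conc=run.dna_conc,
                                  nacl_conc=run.nacl_conc,
                                  absorbance=5.0 * run.absorbance)
        assert (ionic_strength_analysis(run).max_relative_deviation
                == pytest.approx(
                    ionic_strength_analysis(scaled).max_relative_deviation,
                    rel=1e-12))


class TestFtirBandShifts:
    def test_identical_spectra_all_zero(self):
        free, bound, _ = simulate_ftir({})
        res = ftir_band_shifts(free, bound)
        assert all(abs(s.shift) < 1e-9 for s in res.per_band)
        assert not res.at_preference
        assert res.b_conformation_retained
        assert not res.base_contact

    def test_at_bands_moved_six_wavenumbers(self):
        free, bound, _ = simulate_ftir({"A": 6.0, "T": 6.0})
        res = ftir_band_shifts(free, bound)
        assert res.mean_abs_shift_AT == pytest.approx(6.0, abs=0.5)
        assert res.mean_abs_shift_GC == pytest.approx(0.0, abs=0.5)
        assert res.at_preference
        assert res.base_contact
        assert res.b_conformation_retained

    def test_signed_shift_direction(self):
        free, bound, _ = simulate_ftir({"G": -4.0})
        (g,) = [s for s in ftir_band_shifts(free, bound).per_band
                if s.band.name.value == "G"]
        assert g.shift == pytest.approx(-4.0, abs=0.5)

    def test_missing_band_excluded_with_warning(self):
        # grid stops at 1120 cm^-1: the 1085 phosphate band is absent
        free, bound, _ = simulate_ftir({}, grid=(1120.0, 1800.0, 1.0))
        with pytest.warns(UserWarning, match="PO2_asym"):
            res = ftir_band_shifts(free, bound)
        assert any(b.value == "PO2_asym" for b in res.missing_bands)
        # backbone mean computed from the remaining 1225 band
        assert np.isfinite(res.mean_abs_shift_backbone)


def _uv(direction, shift):
    return UVEvidence(direction=direction, peak_shift=shift,
                      max_fractional_change={
                          UVDirection.HYPERCHROMIC: 0.10,
                          UVDirection.HYPOCHROMIC: -0.20,
                          UVDirection.NONE: 0.0}[direction])


class TestClassifyBindingMode:
    def _paper_like_bundle(self):
        visc, _ = simulate_viscosity("groove")
        eb, _ = simulate_displacement(probe_kb=1.4e6, ligand_kb=6.42e3,
                                      probe=Probe.EB, site_conc=1.4e-5)
        rb, _ = simulate_displacement(probe_kb=1e5, ligand_kb=1e5,
                                      probe=Probe.RB, site_conc=2e-6)
        ionic, _ = simulate_ionic_strength(False)
        ftir_free, ftir_bound, _ = simulate_ftir({"A": 5.0, "T": 4.0,
                                                  "G": 1.0, "C": 0.5})
        return EvidenceBundle(
            uv=_uv(UVDirection.HYPERCHROMIC, 0.0),
            viscosity=viscosity_analysis(visc),
            displacements=(displacement_analysis(eb),
                           displacement_analysis(rb)),
            ionic_strength=ionic_strength_analysis(ionic),
            ftir=ftir_band_shifts(ftir_free, ftir_bound),
        )

    def test_groove_pattern_with_rb_displacement_is_minor_groove(self):
        verdict = classify_binding_mode(self._paper_like_bundle())
        assert verdict.mode is BindingMode.MINOR_GROOVE
        assert any("minor-groove probe displaced" in r
                   for r in verdict.rationale)

    def test_intercalation_triple(self):
        visc, _ = simulate_viscosity("intercalator", slope=0.8)
        eb, _ = simulate_displacement(probe_kb=1.4e6, ligand_kb=5e6,
                                      probe=Probe.EB, site_conc=1.4e-5)
        bundle = EvidenceBundle(uv=_uv(UVDirection.HYPOCHROMIC, 8.0),
                                viscosity=viscosity_analysis(visc),
                                displacements=(displacement_analysis(eb),))
        assert classify_binding_mode(bundle).mode is BindingMode.INTERCALATION

    def test_flat_ionic_alone_is_indeterminate(self):
        ionic, _ = simulate_ionic_strength(False)
        bundle = EvidenceBundle(ionic_strength=ionic_strength_analysis(ionic))
        assert classify_binding_mode(bundle).mode is BindingMode.INDETERMINATE

    def test_salt_dependence_gives_electrostatic(self):
        ionic, _ = simulate_ionic_strength(True, drop_frac=0.20)
        visc, _ = simulate_viscosity("groove")
        bundle = EvidenceBundle(viscosity=viscosity_analysis(visc),
                                ionic_strength=ionic_strength_analysis(ionic))
        assert classify_binding_mode(bundle).mode is BindingMode.ELECTROSTATIC

    def test_conflicting_strong_signals_mixed(self):
        visc, _ = simulate_viscosity("intercalator", slope=0.8)
        rb, _ = simulate_displacement(probe_kb=1e5, ligand_kb=1e5,
                                      probe=Probe.RB, site_conc=2e-6)
        bundle = EvidenceBundle(viscosity=viscosity_analysis(visc),
                                displacements=(displacement_analysis(rb),))
        assert classify_binding_mode(bundle).mode is BindingMode.MIXED

    def test_empty_bundle_rejected(self):
        with pytest.raises(errors.InsufficientDataError):
            classify_binding_mode(EvidenceBundle())

    def test_order_independence_and_determinism(self):
        bundle = self._paper_like_bundle()
        swapped = EvidenceBundle(
            uv=bundle.uv, viscosity=bundle.viscosity,
            displacements=tuple(reversed(bundle.displacements)),
            ionic_strength=bundle.ionic_strength, ftir=bundle.ftir)
        v1 = classify_binding_mode(bundle)
        v2 = classify_binding_mode(swapped)
        v3 = classify_binding_mode(bundle)
        assert v1.mode is v2.mode is v3.mode
        assert v1.scores == v2.scores == v3.scores
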