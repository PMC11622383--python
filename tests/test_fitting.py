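import math

import numpy as np
import pytest

from sparselabel import data
from sparselabel.chem import apply_labels, mz, peptide_composition
from sparselabel.fitting import (
    FitResult,
    ObservedSpectrum,
    calibrate_single_point,
    fit_multi_state,
    fit_two_state,
    mass_defect_discriminate,
    measure_fwhm,
)
from sparselabel.isotopes import IsotopePattern, render_profile, simulate_pattern
from sparselabel.states import LabelingState, enumerate_states
from sparselabel.synth import SynthSpec, generate_spectrum, state_patterns


def two_state_profiles(peptide="EEDPIHLR", scheme_labels=(2, 0), fwhm=0.0125):
    comp = peptide_composition(peptide)
    n15N, n13C = scheme_labels
    unlabeled_pattern = simulate_pattern(comp, mode="nominal")
    labeled_pattern = simulate_pattern(
        apply_labels(comp, n13C=n13C, n15N=n15N), mode="nominal"
    )
    grid_lo = unlabeled_pattern.monoisotopic_mass + data.PROTON_MASS - 1.0
    grid = grid_lo + np.arange(int((labeled_pattern.masses[-1] - grid_lo + 3) * 1000)) / 1000.0
    unlabeled = render_profile(unlabeled_pattern, fwhm=fwhm, grid=grid)
    labeled = render_profile(labeled_pattern, fwhm=fwhm, grid=grid)
    return unlabeled, labeled


class TestTwoState:
    def test_exact_mixture_recovered(self):
        unlabeled, labeled = two_state_profiles()
        obs = ObservedSpectrum(
            unlabeled.mz, 0.30 * unlabeled.intensity + 0.70 * labeled.intensity
        )
        result = fit_two_state(obs, unlabeled, labeled)
        assert result.weights[1] == pytest.approx(70.0, abs=0.1)
        assert result.rmse < 1e-12

    def test_pure_unlabeled(self):
        unlabeled, labeled = two_state_profiles()
        obs = ObservedSpectrum(unlabeled.mz, unlabeled.intensity)
        result = fit_two_state(obs, unlabeled, labeled)
        assert result.weights[1] == 0.0

    def test_noisy_mixture_within_two_points(self):
        unlabeled, labeled = two_state_profiles()
        clean = 0.60 * unlabeled.intensity + 0.40 * labeled.intensity
        rng = np.random.default_rng(7)
        noisy = np.clip(clean + rng.normal(0, 0.01 * clean.max(), clean.size), 0, None)
        result = fit_two_state(ObservedSpectrum(unlabeled.mz, noisy), unlabeled, labeled)
        assert result.weights[1] == pytest.approx(40.0, abs=2.0)

    def test_weights_sum_to_100(self):
        unlabeled, labeled = two_state_profiles()
        obs = ObservedSpectrum(
            unlabeled.mz, 0.5 * unlabeled.intensity + 0.5 * labeled.intensity
        )
        result = fit_two_state(obs, unlabeled, labeled)
        assert result.weights.sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_window_rejected(self):
        unlabeled, labeled = two_state_profiles()
        obs = ObservedSpectrum(unlabeled.mz, np.zeros_like(unlabeled.intensity))
        with pytest.raises(ValueError, match="zero intensity"):
            fit_two_state(obs, unlabeled, labeled)

    def test_bad_step_rejected(self):
        unlabeled, labeled = two_state_profiles()
        obs = ObservedSpectrum(unlabeled.mz, unlabeled.intensity)
        with pytest.raises(ValueError, match="step"):
            fit_two_state(obs, unlabeled, labeled, step=-1.0)


class TestMultiState:
    def fit_synthetic(self, peptide, scheme, weights, **kwargs):
        states = enumerate_states(peptide, scheme)
        spec = SynthSpec(peptide=peptide, scheme=scheme, weights=weights, **kwargs)
        obs, truth = generate_spectrum(spec, states)
        patterns = state_patterns(peptide, states, mode=spec.mode)
        result = fit_multi_state(
            obs, states, patterns, fwhm=truth["fwhm"], charge=spec.charge,
            collision_mode=kwargs.get("collision_mode", "first_occurrence"),
        )
        return result, np.asarray(weights)

    def test_noiseless_three_state_recovery(self, vil):
        result, truth = self.fit_synthetic("EEDPIHLR", vil, (40.0, 42.0, 18.0))
        np.testing.assert_allclose(result.weights, truth, atol=0.5)

    def test_fully_labeled_only(self, vil):
        result, truth = self.fit_synthetic("EEDPIHLR", vil, (0.0, 0.0, 100.0))
        np.testing.assert_allclose(result.weights, truth, atol=1e-9)

    def test_fine_structure_five_state_recovery(self, kgs):
        # SAMPEGYVQER under KGS has 6 states incl. one collision at N=2;
        # fine structure + mass-defect mode resolves all of them
        weights = (20.0, 25.0, 15.0, 10.0, 20.0, 10.0)
        result, truth = self.fit_synthetic(
            "SAMPEGYVQER", kgs, weights,
            resolving_power=1_400_000.0, points_per_da=10_000.0, mode="fine",
        )
        # first-occurrence mode cannot see the collided state; use mass defect
        states = enumerate_states("SAMPEGYVQER", kgs)
        spec = SynthSpec(peptide="SAMPEGYVQER", scheme=kgs, weights=weights,
                         resolving_power=1_400_000.0, points_per_da=10_000.0,
                         mode="fine")
        obs, truth_rec = generate_spectrum(spec, states)
        patterns = state_patterns("SAMPEGYVQER", states, mode="fine")
        result = fit_multi_state(obs, states, patterns, fwhm=truth_rec["fwhm"],
                                 collision_mode="mass_defect")
        np.testing.assert_allclose(result.weights, weights, atol=0.5)

    def test_two_state_consistency_with_grid_fit(self, vil):
        # multi-state greedy on a 2-state set agrees with the RMSE grid fit
        peptide, weights = "TISFKDDGTYK", (35.0, 65.0)  # single 15N-Ile
        states = enumerate_states(peptide, vil)
        assert len(states) == 2
        spec = SynthSpec(peptide=peptide, scheme=vil, weights=weights)
        obs, truth = generate_spectrum(spec, states)
        patterns = state_patterns(peptide, states)
        greedy = fit_multi_state(obs, states, patterns, fwhm=truth["fwhm"])
        rendered = [
            render_profile(p, charge=1, fwhm=truth["fwhm"], grid=obs.mz)
            for p in patterns
        ]
        grid_fit = fit_two_state(obs, rendered[0], rendered[1])
        assert abs(greedy.weights[1] - grid_fit.weights[1]) <= 0.1

    def test_skipped_isobaric_state_diagnosed(self, kgs):
        states = enumerate_states("SAMPEGYVQER", kgs)  # collision at N=2
        weights = tuple(
            [100.0 / (len(states) - 1)] * (len(states) - 1) + [0.0]
        )
        # put zero weight on the last state to keep the mixture realizable
        spec = SynthSpec(peptide="SAMPEGYVQER", scheme=kgs,
                         weights=(30.0, 30.0, 40.0, 0.0, 0.0, 0.0))
        obs, truth = generate_spectrum(spec, states)
        patterns = state_patterns("SAMPEGYVQER", states)
        result = fit_multi_state(obs, states, patterns, fwhm=truth["fwhm"])
        assert any("isobaric" in d for d in result.diagnostics)

    def test_absent_state_gets_zero_and_diagnostic(self, vil):
        result, truth = self.fit_synthetic("EEDPIHLR", vil, (60.0, 0.0, 40.0))
        assert result.weights[1] == pytest.approx(0.0, abs=0.2)

    def test_monotonicity(self, vil):
        recovered = []
        for w in (10.0, 30.0, 50.0):
            result, _ = self.fit_synthetic("EEDPIHLR", vil, (60.0 - w / 2, w, 40.0 - w / 2))
            recovered.append(result.weights[1])
        assert recovered == sorted(recovered)

    def test_combination_never_fits_worse_than_single_state(self, vil):
        peptide, weights = "EEDPIHLR", (40.0, 42.0, 18.0)
        states = enumerate_states(peptide, vil)
        spec = SynthSpec(peptide=peptide, scheme=vil, weights=weights)
        obs, truth = generate_spectrum(spec, states)
        patterns = state_patterns(peptide, states)
        combined = fit_multi_state(obs, states, patterns, fwhm=truth["fwhm"])
        grid = obs.mz
        window = slice(0, len(grid))
        for pattern in patterns:
            single = render_profile(pattern, charge=1, fwhm=truth["fwhm"], grid=grid)
            scale = float(single.intensity @ obs.intensity) / float(
                single.intensity @ single.intensity
            )
            resid = obs.intensity - scale * single.intensity
            rmse = math.sqrt(float(resid @ resid) / len(grid))
            assert combined.rmse <= rmse + 1e-12

    def test_weights_always_sum_to_100(self, vil):
        for weights in [(100.0, 0.0, 0.0), (20.0, 30.0, 50.0), (0.0, 99.0, 1.0)]:
            result, _ = self.fit_synthetic("EEDPIHLR", vil, weights)
            assert result.weights.sum() == pytest.approx(100.0, abs=1e-6)

    def test_fitresult_rejects_bad_weights(self):
        from sparselabel.isotopes import Profile

        profile = Profile(start=0.0, spacing=1.0, intensity=np.zeros(3))
        with pytest.raises(ValueError, match="not 100"):
            FitResult(["a"], np.array([50.0]), np.array([1.0]), 0.0, profile, 0.01)


class TestMeasureFwhm:
    def test_known_gaussian(self):
        sigma = 0.01
        x = 499.0 + np.arange(20000) * 1e-4
        y = np.exp(-0.5 * ((x - 500.0) / sigma) ** 2)
        fwhm = measure_fwhm(ObservedSpectrum(x, y), 500.0)
        assert fwhm == pytest.approx(2.3548 * sigma, rel=0.01)

    def test_rendered_profile_at_80k(self):
        pattern = IsotopePattern([1000.0 - data.PROTON_MASS], [1.0], [0], "nominal")
        profile = render_profile(pattern, fwhm=0.0125, points_per_da=10_000)
        got = measure_fwhm(ObservedSpectrum(profile.mz, profile.intensity), 1000.0)
        assert got == pytest.approx(0.0125, abs=2e-4)

    def test_flat_spectrum_rejected(self):
        x = np.linspace(500, 501, 100)
        with pytest.raises(ValueError):
            measure_fwhm(ObservedSpectrum(x, np.zeros_like(x)), 500.5)


class TestCalibration:
    def make_peak(self, center, shift_ppm=0.0):
        x = (center - 0.5) + np.arange(10000) * 1e-4
        y = np.exp(-0.5 * ((x - center) / 0.01) ** 2)
        return ObservedSpectrum(x * (1 + shift_ppm * 1e-6), y)

    def test_identity_when_exact(self):
        obs = self.make_peak(800.0)
        out = calibrate_single_point(obs, 800.0)
        np.testing.assert_allclose(out.mz, obs.mz, rtol=1e-10)

    def test_corrects_global_ppm_shift(self):
        obs = self.make_peak(800.0, shift_ppm=5.0)
        out = calibrate_single_point(obs, 800.0)
        apex = out.mz[np.argmax(out.intensity)]
        assert abs(apex - 800.0) / 800.0 * 1e6 < 0.01

    def test_scale_factor(self):
        obs = self.make_peak(800.0, shift_ppm=2.0)
        out = calibrate_single_point(obs, 800.0)
        factor = out.mz[0] / obs.mz[0]
        assert factor == pytest.approx(1.0 / (1 + 2e-6), rel=1e-9)

    def test_no_peak_rejected(self):
        obs = self.make_peak(800.0)
        with pytest.raises(ValueError, match="reference"):
            calibrate_single_point(obs, 900.0)


class TestMassDefect:
    CANDIDATES = [LabelingState(3, 0), LabelingState(1, 2)]

    def test_theoretical_separation(self):
        n3 = 3 * data.N15_SHIFT
        n1c2 = data.N15_SHIFT + 2 * data.C13_SHIFT
        assert n1c2 - n3 == pytest.approx(0.0126398, abs=1e-7)

    def test_true_candidate_scores_smaller_error(self, kgs):
        base = peptide_composition("YFHHNSDFYIPK")
        truth = apply_labels(base, n13C=2, n15N=1)  # [15N,13C2]
        pattern = simulate_pattern(truth, mode="nominal")
        profile = render_profile(pattern, charge=1, fwhm=0.012, points_per_da=10_000)
        obs = calibrate_single_point(
            ObservedSpectrum(profile.mz, profile.intensity), mz(truth, 1)
        )
        errors = mass_defect_discriminate(obs, base, self.CANDIDATES)
        assert abs(errors["[15N, 13C2]"]) < abs(errors["[15N3]"])
        assert abs(errors["[15N, 13C2]"]) < 1.0  # sub-ppm after calibration

    def test_identical_candidates_equal_error(self, kgs):
        base = peptide_composition("YFHHNSDFYIPK")
        truth = apply_labels(base, n13C=2, n15N=1)
        pattern = simulate_pattern(truth, mode="nominal")
        profile = render_profile(pattern, charge=1, fwhm=0.012)
        obs = ObservedSpectrum(profile.mz, profile.intensity)
        first = mass_defect_discriminate(obs, base, [LabelingState(1, 2)])
        second = mass_defect_discriminate(obs, base, [LabelingState(1, 2, extra=True)])
        assert first["[15N, 13C2]"] == pytest.approx(second["[15N, 13C2]"], abs=1e-12)

    def test_absent_peak_indeterminate(self):
        base = peptide_composition("YFHHNSDFYIPK")
        x = np.linspace(100.0, 101.0, 200)
        obs = ObservedSpectrum(x, np.ones_like(x) * 0.0)
        errors = mass_defect_discriminate(obs, base, self.CANDIDATES)
        assert all(v is None for v in errors.values())

    def test_mixed_neutron_counts_rejected(self):
        base = peptide_composition("YFHHNSDFYIPK")
        x = np.linspace(100.0, 101.0, 200)
        obs = ObservedSpectrum(x, np.zeros_like(x))
        with pytest.raises(ValueError, match="neutron"):
            mass_defect_discriminate(
                obs, base, [LabelingState(1, 0), LabelingState(1, 2)]
            )
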