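"""Line shapes, weighting window, weighted RMSD/similarity, and the fit."""

import numpy as np
import pytest

from enref import (
    ContinuousSpectrum,
    ConvolutionParams,
    ImpulseSpectrum,
    SpectrumError,
    WeightWindow,
    autoconvolute,
    convolute,
    ensemble_spectrum,
    make_spectrum_pair,
    read_xy,
    similarity,
    weight_function,
    weighted_rmsd,
    write_xy,
)

GRID_IR = np.linspace(800.0, 1200.0, 4001)


class TestConvolute:
    def test_lorentzian_peak_and_half_maximum(self):
        imp = ImpulseSpectrum("IR", [1000.0], [1.0])
        curve = convolute(imp, ConvolutionParams(gamma=10.0, shift=1.0), GRID_IR)
        at = lambda x: np.interp(x, curve.grid, curve.values)  # noqa: E731
        assert at(1000.0) == pytest.approx(1.0, abs=1e-6)
        assert at(1005.0) == pytest.approx(0.5, abs=1e-6)
        assert at(995.0) == pytest.approx(0.5, abs=1e-6)

    def test_gaussian_peak_and_fwhm_identities(self):
        gamma = 2.0 * np.sqrt(2.0 * np.log(2.0))  # σ = 1
        imp = ImpulseSpectrum("UV", [300.0], [1.0])
        grid = np.linspace(280.0, 320.0, 8001)
        curve = convolute(imp, ConvolutionParams(gamma=gamma, shift=0.0), grid)
        at = lambda x: np.interp(x, curve.grid, curve.values)  # noqa: E731
        assert at(300.0) == pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-6)
        assert at(300.0 + gamma / 2) == pytest.approx(0.5 / np.sqrt(2 * np.pi), abs=1e-6)
        assert at(300.0 - gamma / 2) == pytest.approx(0.5 / np.sqrt(2 * np.pi), abs=1e-6)

    def test_numerically_measured_fwhm_equals_gamma(self):
        imp = ImpulseSpectrum("UV", [300.0], [1.0])
        grid = np.linspace(250.0, 350.0, 100001)
        gamma = 7.3
        curve = convolute(imp, ConvolutionParams(gamma=gamma, shift=0.0), grid)
        half = curve.values.max() / 2.0
        above = grid[curve.values >= half]
        assert above[-1] - above[0] == pytest.approx(gamma, abs=2e-3)

    def test_linearity_over_impulses(self):
        params = ConvolutionParams(gamma=8.0, shift=1.0)
        a = ImpulseSpectrum("IR", [950.0], [0.7])
        b = ImpulseSpectrum("IR", [1100.0], [0.3])
        both = ImpulseSpectrum("IR", [950.0, 1100.0], [0.7, 0.3])
        y = convolute(both, params, GRID_IR).values
        np.testing.assert_allclose(
            y, convolute(a, params, GRID_IR).values + convolute(b, params, GRID_IR).values,
            atol=1e-12,
        )

    def test_multiplicative_shift_moves_vibrational_stick(self):
        imp = ImpulseSpectrum("IR", [1000.0], [1.0])
        curve = convolute(imp, ConvolutionParams(gamma=10.0, shift=0.98), GRID_IR)
        assert curve.grid[np.argmax(curve.values)] == pytest.approx(980.0, abs=0.1)

    def test_negative_additive_shift_is_a_blue_shift(self):
        imp = ImpulseSpectrum("UV", [300.0], [1.0])
        grid = np.linspace(250.0, 350.0, 2001)
        curve = convolute(imp, ConvolutionParams(gamma=10.0, shift=-20.0), grid)
        assert curve.grid[np.argmax(curve.values)] == pytest.approx(280.0, abs=0.1)

    def test_achiral_kind_rejects_negative_intensity(self):
        with pytest.raises(SpectrumError):
            ImpulseSpectrum("IR", [1000.0], [-1.0])
        ImpulseSpectrum("VCD", [1000.0], [-1.0])  # chiral: allowed

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(SpectrumError):
            ConvolutionParams(gamma=0.0)


class TestEnsembleSpectrum:
    def test_single_conformer_identity(self):
        imp = ImpulseSpectrum("IR", [1000.0, 1050.0], [1.0, 0.5])
        params = ConvolutionParams(gamma=8.0)
        np.testing.assert_allclose(
            ensemble_spectrum([imp], [1.0], params, GRID_IR).values,
            convolute(imp, params, GRID_IR).values,
        )

    def test_convexity_over_identical_conformers(self):
        imp = ImpulseSpectrum("IR", [1000.0], [1.0])
        params = ConvolutionParams(gamma=8.0)
        mix = ensemble_spectrum([imp, imp], [0.5, 0.5], params, GRID_IR)
        np.testing.assert_allclose(mix.values, convolute(imp, params, GRID_IR).values)

    def test_pointwise_weighted_sum_oracle(self):
        a = ImpulseSpectrum("IR", [950.0], [1.0])
        b = ImpulseSpectrum("IR", [1100.0], [1.0])
        params = ConvolutionParams(gamma=8.0)
        mix = ensemble_spectrum([a, b], [2 / 3, 1 / 3], params, GRID_IR)
        expected = (
            2 / 3 * convolute(a, params, GRID_IR).values
            + 1 / 3 * convolute(b, params, GRID_IR).values
        )
        np.testing.assert_allclose(mix.values, expected, atol=1e-14)

    def test_permutation_invariance(self):
        a = ImpulseSpectrum("IR", [950.0], [1.0])
        b = ImpulseSpectrum("IR", [1100.0], [0.4])
        params = ConvolutionParams(gamma=8.0)
        np.testing.assert_allclose(
            ensemble_spectrum([a, b], [0.7, 0.3], params, GRID_IR).values,
            ensemble_spectrum([b, a], [0.3, 0.7], params, GRID_IR).values,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpectrumError):
            ensemble_spectrum(
                [ImpulseSpectrum("IR", [1000.0], [1.0])], [0.5, 0.5],
                ConvolutionParams(gamma=8.0), GRID_IR,
            )


class TestWeightFunction:
    WIN = WeightWindow(x_exp_min=900.0, x_exp_max=1700.0, x_int_min=1000.0, x_int_max=1600.0)

    def test_interior_is_one(self):
        assert weight_function(1300.0, self.WIN) == 1.0

    def test_outside_experimental_window_is_zero(self):
        assert weight_function(850.0, self.WIN) == 0.0
        assert weight_function(1750.0, self.WIN) == 0.0

    def test_floor_activates_deep_in_taper(self):
        # at 3σ1 into the taper the Gaussian is exp(−4.5) ≈ 0.0111 < 0.15
        x = 1000.0 - 3.0 * self.WIN.sigma1
        assert np.exp(-4.5) < 0.15
        assert weight_function(x, self.WIN) == pytest.approx(0.15)

    def test_taper_is_normalized_gaussian_above_floor(self):
        x = 1000.0 - 0.5 * self.WIN.sigma1
        assert weight_function(x, self.WIN) == pytest.approx(np.exp(-0.125), rel=1e-12)

    def test_continuity_at_interior_bounds(self):
        for bound in (1000.0, 1600.0):
            inside = weight_function(bound, self.WIN)
            just_out = weight_function(bound - 1e-9 if bound == 1000.0 else bound + 1e-9, self.WIN)
            assert inside == 1.0
            assert just_out == pytest.approx(1.0, abs=1e-9)

    def test_disabled_window_is_step_function(self):
        win = WeightWindow(x_exp_min=900.0, x_exp_max=1700.0, enabled=False)
        xs = np.array([850.0, 900.0, 1300.0, 1700.0, 1750.0])
        np.testing.assert_array_equal(weight_function(xs, win), [0, 1, 1, 1, 0])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(SpectrumError):
            WeightWindow(x_exp_min=900.0, x_exp_max=1700.0, x_int_min=1650.0, x_int_max=1000.0)


class TestWeightedRmsdAndSimilarity:
    def test_identical_spectra_zero(self):
        grid = np.linspace(0, 1, 100)
        s = ContinuousSpectrum(grid, np.sin(grid * 6) + 2)
        win = WeightWindow(0.0, 1.0, enabled=False)
        assert weighted_rmsd(s, s, win) == pytest.approx(0.0, abs=1e-15)
        assert similarity(0.0, chiral=False) == 1.0

    def test_antipodal_chiral_spectra_reach_two(self):
        grid = np.linspace(0, 1, 50)
        y = np.where(grid < 0.5, 1.0, -1.0)
        a = ContinuousSpectrum(grid, y)
        b = ContinuousSpectrum(grid, -y)
        win = WeightWindow(0.0, 1.0, enabled=False)
        rmsd = weighted_rmsd(a, b, win)
        assert rmsd == pytest.approx(2.0)
        assert similarity(rmsd, chiral=True) == pytest.approx(0.0)

    def test_hand_computed_five_point_case(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        # both arrays already have max|y| = 1, so normalisation is the identity
        y = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
        ye = np.array([1.0, 0.6, 0.1, -0.4, -0.9])
        w = np.array([0.15, 1.0, 1.0, 1.0, 0.15])
        expected = np.sqrt(np.sum(w * (y - ye) ** 2) / w.sum())
        calc = ContinuousSpectrum(grid, y)
        exp = ContinuousSpectrum(grid, ye)
        got = np.sqrt(
            np.sum(w * (calc.normalized().values - exp.normalized().values) ** 2) / w.sum()
        )
        # both arrays are already max-normalised, so this is the formula itself
        assert got == pytest.approx(expected, rel=1e-12)
        # the library value with uniform weights matches the plain RMS
        win = WeightWindow(0.0, 4.0, enabled=False)
        assert weighted_rmsd(calc, exp, win) == pytest.approx(
            np.sqrt(np.mean((y - ye) ** 2)), rel=1e-12
        )

    def test_similarity_clipped_and_scaled(self):
        assert similarity(0.25, chiral=False) == pytest.approx(0.75)
        assert similarity(1.0, chiral=True) == pytest.approx(0.5)
        assert similarity(5.0, chiral=False) == 0.0

    def test_no_window_overlap_raises(self):
        grid = np.linspace(0, 1, 10)
        s = ContinuousSpectrum(grid, np.ones(10))
        win = WeightWindow(5.0, 6.0, enabled=False)
        with pytest.raises(SpectrumError):
            weighted_rmsd(s, s, win)


class TestAutoconvolute:
    def test_parameter_recovery_noiseless(self):
        imp, exp, truth = make_spectrum_pair(9.0, 0.985, kind="IR", seed=3)
        fit = autoconvolute([imp], [1.0], exp, gamma_bounds=(2, 24), shift_bounds=(0.94, 1.02))
        assert fit.gamma == pytest.approx(truth["gamma"], rel=0.01)
        assert fit.shift == pytest.approx(truth["shift"], rel=0.01)
        assert fit.similarity >= 0.999

    def test_fixed_point_at_truth(self):
        imp, exp, _ = make_spectrum_pair(8.0, 1.0, kind="IR", seed=1)
        fit = autoconvolute([imp], [1.0], exp, gamma_bounds=(7.9, 8.1), shift_bounds=(0.999, 1.001))
        assert fit.rmsd < 1e-6
        assert fit.converged

    def test_bounds_pin_excluded_truth(self):
        imp, exp, _ = make_spectrum_pair(20.0, 1.0, kind="IR", seed=2)
        fit = autoconvolute([imp], [1.0], exp, gamma_bounds=(2.0, 10.0), shift_bounds=(0.99, 1.01))
        assert fit.gamma == pytest.approx(10.0, abs=1e-6)

    def test_gaussian_domain_recovery(self):
        imp, exp, truth = make_spectrum_pair(12.0, -15.0, kind="ECD", seed=4)
        fit = autoconvolute([imp], [1.0], exp, gamma_bounds=(5, 60), shift_bounds=(-50, 50))
        assert fit.gamma == pytest.approx(truth["gamma"], rel=0.01)
        assert fit.shift == pytest.approx(truth["shift"], abs=abs(truth["shift"]) * 0.01)


class TestXYio:
    def test_round_trip_and_comma_separation(self, tmp_path):
        path = tmp_path / "spec.xy"
        path.write_text("2.0, 0.5\n0.0, 1.0\n1.0, 0.8\n# comment\n")
        spec = read_xy(path)
        assert spec.grid[0] == 0.0 and spec.grid[-1] == 2.0
        assert np.interp(1.0, spec.grid, spec.values) == pytest.approx(0.8, abs=1e-3)
        out = tmp_path / "out.xy"
        write_xy(spec, out)
        back = read_xy(out)
        np.testing.assert_allclose(back.values, spec.values, atol=1e-6)

    def test_single_point_file_rejected(self, tmp_path):
        path = tmp_path / "one.xy"
        path.write_text("1.0 2.0\n")
        with pytest.raises(SpectrumError):
            read_xy(path)
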