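import warnings

import numpy as np
import pytest

from stemftir.emsc import (
    ComponentLibrary,
    build_model,
    correct_spectrum,
    fit_cube,
    fit_spectrum,
    pca_scores,
)
from stemftir.io_spectra import HyperCube, SampleMeta, SpectrumTable, WavenumberAxis
from stemftir.synth import SynthConfig, make_cube, make_emsc_mixtures


class TestBuildModel:
    def test_single_reference_spectrum_is_m_bar(self, library):
        s = library.spectra[0] * 2.0 + 0.1
        model = build_model(s[None, :], library, poly_order=1)
        np.testing.assert_array_equal(model.m_bar, s)

    def test_poly_order_zero_design_width(self, library):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0.1, 1.0, (3, len(library.axis)))
        model = build_model(ref, library, poly_order=0)
        assert model.design.shape[1] == 2 + library.n_components

    def test_duplicate_component_is_rank_deficiency_error(self, library):
        dup = ComponentLibrary(
            library.axis,
            ["a", "b"],
            ["other", "other"],
            np.vstack([library.spectra[0], library.spectra[0]]),
        )
        with pytest.raises(ValueError, match="rank"):
            build_model(np.ones((1, len(library.axis))), dup, poly_order=1)

    def test_near_collinear_reference_warns_not_raises(self, library):
        # m_bar that is exactly a component mixture sits in the design span
        ref = (np.ones(library.n_components) @ library.spectra)[None, :]
        with pytest.warns(RuntimeWarning, match="condition"):
            model = build_model(ref, library, poly_order=2)
        assert model.condition_number > 1e8


class TestFitSpectrum:
    def test_noiseless_recovery_to_machine_precision(self, oracle_model):
        m = oracle_model
        s = 1.3 * m.m_bar + 0.2 * m.design[:, 1] + 0.5 * m.design[:, m.poly_order + 3]
        fit = fit_spectrum(m, s)
        assert abs(fit.a - 1.3) < 1e-9
        assert abs(fit.baseline[0] - 0.2) < 1e-9
        expected_c = np.zeros(m.n_components)
        expected_c[1] = 0.5
        np.testing.assert_allclose(fit.components, expected_c, atol=1e-9)

    def test_reference_spectrum_maps_to_unit_scale(self, oracle_model):
        fit = fit_spectrum(oracle_model, oracle_model.m_bar)
        assert abs(fit.a - 1.0) < 1e-9
        np.testing.assert_allclose(fit.baseline, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.components, 0.0, atol=1e-9)

    def test_relative_absorbance_scale_invariant(self, oracle_model):
        spectra, _ = make_emsc_mixtures(oracle_model, 3, seed=5, snr_db=40.0)
        for s in spectra:
            ra1 = fit_spectrum(oracle_model, s).relative_absorbance
            ra2 = fit_spectrum(oracle_model, 7.3 * s).relative_absorbance
            for name in ra1:
                assert ra1[name] == pytest.approx(ra2[name], abs=1e-12)

    def test_relative_absorbance_sums_to_one(self, oracle_model):
        spectra, _ = make_emsc_mixtures(oracle_model, 5, seed=6, snr_db=30.0)
        for s in spectra:
            assert sum(fit_spectrum(oracle_model, s).relative_absorbance.values()) == (
                pytest.approx(1.0, abs=1e-9)
            )

    def test_pls_full_rank_equals_ols(self, oracle_model):
        spectra, _ = make_emsc_mixtures(oracle_model, 3, seed=7, snr_db=40.0)
        for s in spectra:
            ols = fit_spectrum(oracle_model, s, solver="ols")
            pls = fit_spectrum(oracle_model, s, solver="pls")
            np.testing.assert_allclose(pls.components, ols.components, atol=1e-8)
            assert pls.a == pytest.approx(ols.a, abs=1e-8)

    def test_nnls_component_coefficients_nonnegative(self, oracle_model):
        spectra, _ = make_emsc_mixtures(oracle_model, 5, seed=8, snr_db=20.0)
        for s in spectra:
            fit = fit_spectrum(oracle_model, s, solver="nnls_components")
            assert np.all(fit.components >= -1e-12)

    def test_noise_ladder_rmse_monotone(self, oracle_model):
        """Chemical-loading RMSE decreases as the noise level decreases."""
        m = oracle_model
        sl = slice(m.poly_order + 2, None)
        rmses = []
        for snr in (20.0, 35.0, 50.0):
            spectra, theta = make_emsc_mixtures(m, 60, seed=9, snr_db=snr)
            t_true = theta[:, sl] + theta[:, :1] * m.ref_loadings[None, :]
            t_hat = np.array([fit_spectrum(m, s).chemical_loadings for s in spectra])
            rmses.append(float(np.sqrt(np.mean((t_hat - t_true) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_non_finite_input_rejected(self, oracle_model):
        s = oracle_model.m_bar.copy()
        s[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_spectrum(oracle_model, s)


class TestCorrectSpectrum:
    def test_scaled_plus_offset_maps_back_to_reference(self, oracle_model):
        s = 2.0 * oracle_model.m_bar + 0.1
        fit = fit_spectrum(oracle_model, s)
        np.testing.assert_allclose(
            correct_spectrum(oracle_model, fit, s), oracle_model.m_bar, atol=1e-9
        )

    def test_reference_unchanged(self, oracle_model):
        s = oracle_model.m_bar
        fit = fit_spectrum(oracle_model, s)
        np.testing.assert_allclose(correct_spectrum(oracle_model, fit, s), s, atol=1e-9)

    def test_noiseless_mixture_corrects_to_scaled_chemistry(self, oracle_model):
        """Correction removes the baseline: the result is the chemical part
        (reference + components) at unit scale, checked algebraically."""
        m = oracle_model
        spectra, theta = make_emsc_mixtures(m, 4, seed=11)
        for s, th in zip(spectra, theta):
            fit = fit_spectrum(m, s)
            chem = th[0] * m.m_bar + m.design[:, m.poly_order + 2 :] @ th[m.poly_order + 2 :]
            np.testing.assert_allclose(
                correct_spectrum(m, fit, s), chem / th[0], atol=1e-8
            )


class TestFitCube:
    def test_uniform_cube_gives_constant_maps(self, oracle_model):
        s = oracle_model.design @ np.concatenate(
            ([1.1], [0.01, 0.0, 0.0], np.linspace(0.2, 0.9, oracle_model.n_components))
        )
        data = np.tile(s, (3, 4, 1))
        cube = HyperCube(oracle_model.axis, data)
        result = fit_cube(oracle_model, cube)
        for j in range(oracle_model.n_components):
            band = result.relative_absorbance[:, :, j]
            assert np.ptp(band) < 1e-10

    def test_two_region_recovery_within_five_percent(self, library):
        cfg = SynthConfig(seed=4, layout="blocks", image_size=(24, 24), n_blocks=2)
        cube, truth = make_cube(cfg, library)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = build_model(cube.masked_spectra(), library, poly_order=2)
            result = fit_cube(model, cube)
        for region in (1, 2):
            member = truth.region_labels == region
            w = truth.region_profiles[region]
            expected = w / w.sum()
            got = np.nanmean(result.relative_absorbance[member], axis=0)
            np.testing.assert_allclose(got, expected, rtol=0.05, atol=0.005)

    def test_fully_masked_cube_warns_and_returns_empty(self, oracle_model):
        cube = HyperCube(
            oracle_model.axis,
            np.ones((2, 2, len(oracle_model.axis))),
            mask=np.zeros((2, 2), dtype=bool),
        )
        with pytest.warns(RuntimeWarning, match="masked"):
            result = fit_cube(oracle_model, cube)
        assert np.isnan(result.relative_absorbance).all()


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        axis = WavenumberAxis(np.array([1300.0, 1200.0, 1100.0]))
        t = np.linspace(0, 1, 8)
        X = np.outer(t, [1.0, 2.0, 3.0]) + 0.5
        table = SpectrumTable(axis, X, [SampleMeta(f"s{i}") for i in range(8)])
        _, _, evr = pca_scores(table, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        cov = np.array([[4.0, 1.0, 0.0], [1.0, 2.0, 0.3], [0.0, 0.3, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=40)
        axis = WavenumberAxis(np.array([1300.0, 1200.0, 1100.0]))
        table = SpectrumTable(axis, X + 5.0, [SampleMeta(f"s{i}") for i in range(40)])
        scores, loadings, evr = pca_scores(table, 3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(evr, evals[order] / evals.sum(), atol=1e-12)
        for i in range(3):
            v = evecs[:, order[i]]
            assert abs(abs(loadings[i] @ v) - 1.0) < 1e-10

    def test_sign_convention_largest_loading_positive(self, library):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 1.0, (12, len(library.axis)))
        table = SpectrumTable(
            library.axis, X, [SampleMeta(f"s{i}") for i in range(12)]
        )
        _, loadings, _ = pca_scores(table, 3)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_components_rejected(self, small_table):
        with pytest.raises(ValueError):
            pca_scores(small_table, 3)


class TestLibraryCsv:
    def test_roundtrip(self, library, tmp_path):
        path = library.to_csv(tmp_path / "lib.csv")
        back = ComponentLibrary.from_csv(path)
        assert back.names == library.names
        assert back.categories == library.categories
        np.testing.assert_array_equal(back.spectra, library.spectra)
        np.testing.assert_array_equal(back.axis.values, library.axis.values)
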