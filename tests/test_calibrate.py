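"""Split, RC wavelength selection, MLR fit and evaluation metrics."""

import numpy as np
import pytest

from nirshelf.calibrate import (
    MLRCalibration,
    SplitSpec,
    compare_pretreatments,
    evaluate,
    fit_mlr,
    predict_vcc,
    select_wavenumbers_rc,
    split_samples,
)
from nirshelf.errors import CollinearityError, SelectionError, SplitError
from nirshelf.grid import LWNIR
from nirshelf.io import make_spectra_set
from nirshelf.reference import REFERENCE_MLR_INTERCEPT, reference_mlr_model
from nirshelf.synth import SyntheticStudyConfig, generate_study


class TestSplit:
    def test_default_split_partitions_non_decayed(self, default_study):
        cal, pred = split_samples(default_study, SplitSpec(seed=4))
        assert len(cal) == 50 and len(pred) == 17
        assert not set(cal) & set(pred)
        eligible = set(
            default_study.manifest.loc[~default_study.manifest["decayed"], "fruit"]
        )
        assert set(cal) | set(pred) == eligible  # 67 = 72 - 5 decayed

    def test_same_seed_same_split(self, default_study):
        assert split_samples(default_study, SplitSpec(seed=9)) == split_samples(
            default_study, SplitSpec(seed=9)
        )

    def test_insufficient_samples(self, small_study):
        with pytest.raises(SplitError):
            split_samples(small_study, SplitSpec(n_calibration=50, n_prediction=17))


class TestSelection:
    def test_single_informative_column(self, rng):
        X = rng.normal(size=(40, 30))
        wn = np.linspace(9000, 4000, 30)
        y = 3.0 * X[:, 12]
        assert select_wavenumbers_rc(X, y, wn, 1) == [wn[12]]

    def test_planted_bands_recovered(self, noise_free_study):
        from nirshelf.calibrate import assemble_calibration
        from nirshelf.synth import VCC_COUPLED_CENTERS

        spectra, y = assemble_calibration(noise_free_study)
        _, ridx = spectra.grid.restrict(LWNIR.lo, LWNIR.hi)
        selected = select_wavenumbers_rc(
            spectra.values[:, ridx], y.to_numpy(), spectra.grid.wavenumbers[ridx], 5
        )
        for got, planted in zip(selected, sorted(VCC_COUPLED_CENTERS, reverse=True)):
            assert abs(got - planted) <= spectra.grid.spacing

    def test_tie_breaks_to_lower_wavenumber(self):
        # two mirror-image peaks of identical |RC|
        wn = np.linspace(100, 10, 7)
        rng = np.random.default_rng(2)
        base = rng.normal(size=(50, 7)) * 0.0
        z = rng.normal(size=50)
        X = base.copy()
        X[:, 1] = z
        X[:, 5] = z  # same signal at two wavenumbers -> equal coefficients
        y = z
        chosen = select_wavenumbers_rc(X, y, wn, 1)
        assert chosen == [wn[5]]  # lower wavenumber wins

    def test_too_few_maxima_reported(self, rng):
        X = rng.normal(size=(30, 10))
        y = X[:, 4]
        with pytest.raises(SelectionError, match="local maxima"):
            select_wavenumbers_rc(X, y, np.linspace(90, 9, 10), 9)


class TestMLRFit:
    def test_exact_affine_recovery(self, rng):
        X = rng.normal(size=(50, 3))
        beta = np.array([2.0, -1.5, 0.5])
        y = 7.0 + X @ beta
        model = fit_mlr(X, y)
        assert model.intercept_ == pytest.approx(7.0, abs=1e-8)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        model = fit_mlr(X, y)
        D = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert model.intercept_ == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-8)

    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import LinearRegression

        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        model = fit_mlr(X, y)
        sk = LinearRegression().fit(X, y)
        assert model.intercept_ == pytest.approx(sk.intercept_, abs=1e-10)
        np.testing.assert_allclose(model.coef_, sk.coef_, atol=1e-10)

    def test_collinear_design_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(CollinearityError):
            fit_mlr(X, rng.normal(size=30))

    def test_ci_mean_brackets_mean_of_fitted(self, rng):
        X = rng.normal(size=(50, 3))
        y = 5.0 + X @ np.array([1.0, 2.0, 3.0]) + rng.normal(0, 0.5, 50)
        model = fit_mlr(X, y)
        lo, hi = model.ci_mean_
        fitted_mean = float(np.mean(model.predict(X)))
        assert lo < fitted_mean < hi


class TestReferenceModelArithmetic:
    """The published five-wavenumber calibration evaluated directly."""

    def test_intercept_at_zero_absorbance(self):
        model = reference_mlr_model()
        assert predict_vcc(model, np.zeros(5))[0] == pytest.approx(REFERENCE_MLR_INTERCEPT)

    def test_single_band_contribution(self):
        model = reference_mlr_model()
        x = np.zeros(5)
        x[2] = 1.0  # the 5,666 cm^-1 coefficient is -3501.009
        assert predict_vcc(model, x)[0] == pytest.approx(1409.098 - 3501.009)

    def test_zero_coefficients_give_intercept(self):
        model = MLRCalibration.from_coefficients(42.0, np.zeros(3), [900.0, 800.0, 700.0])
        np.testing.assert_allclose(predict_vcc(model, np.ones((4, 3))), 42.0)

    def test_lookup_on_grid(self, grid):
        # reference wavenumbers are generally off the 8 cm^-1 grid; the
        # model must refuse silently mismatched grids
        from nirshelf.errors import GridMismatchError

        model = reference_mlr_model()
        spectra = make_spectra_set(grid, np.zeros((1, len(grid))), [("F01", 1, 1)])
        with pytest.raises(GridMismatchError):
            predict_vcc(model, spectra)

    def test_lookup_on_matching_grid(self):
        from nirshelf.grid import SpectrumGrid

        wn = np.arange(9000, 4000 - 1, -2, dtype=float)
        sg = SpectrumGrid(wn)
        model = reference_mlr_model()
        values = np.zeros((1, len(sg)))
        spectra = make_spectra_set(sg, values, [("F01", 1, 1)])
        assert predict_vcc(model, spectra)[0] == pytest.approx(REFERENCE_MLR_INTERCEPT)


class TestEvaluate:
    def test_perfect_fit(self, rng):
        X = rng.normal(size=(30, 2))
        y = 1.0 + X @ np.array([2.0, 3.0])
        model = fit_mlr(X, y)
        m = evaluate(model, X, y, X, y)
        assert m.rc == pytest.approx(1.0)
        assert m.rmsec == pytest.approx(0.0, abs=1e-9)

    def test_shifted_predictions(self, rng):
        X = rng.normal(size=(30, 2))
        y = 1.0 + X @ np.array([2.0, 3.0])
        model = fit_mlr(X, y + 4.0)  # predictions = y + 4 exactly
        m = evaluate(model, X, y, X, y)
        assert m.rc == pytest.approx(1.0)
        assert m.rmsec == pytest.approx(4.0)
        assert m.rmsep == pytest.approx(4.0)

    def test_hand_computed_pearson_rmse(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        meas = np.array([1.1, 1.9, 3.2, 3.8])
        model = MLRCalibration.from_coefficients(0.0, np.ones(1), [5000.0])
        m = evaluate(model, pred[:, None], meas, pred[:, None], meas)
        # hand Pearson: r = cov / (sd*sd)
        r_hand = float(np.corrcoef(pred, meas)[0, 1])
        rmse_hand = float(np.sqrt(np.mean((pred - meas) ** 2)))
        assert m.rc == pytest.approx(r_hand)
        assert m.rmsec == pytest.approx(rmse_hand)

    def test_constant_predictions_flagged(self):
        model = MLRCalibration.from_coefficients(10.0, np.zeros(1), [5000.0])
        X = np.ones((5, 1))
        y = np.arange(5.0)
        m = evaluate(model, X, y, X, y)
        assert m.undefined_correlation
        assert np.isnan(m.rc)


class TestComparePretreatments:
    def test_noise_free_all_methods_near_perfect(self, noise_free_study):
        table = compare_pretreatments(
            noise_free_study,
            methods=("raw", "sg", "msc", "d1", "d2"),
            region="LWNIR",
            n_select=1,  # noise-free absorbances are collinear across bands
            split=SplitSpec(seed=1),
        )
        assert list(table.index) == ["raw", "sg", "msc", "d1", "d2"]
        # per-spectrum linear operators leave absorbance affine in vcc
        assert (table.loc[["raw", "sg", "d1", "d2"], "Rc"] > 0.999).all()
        # MSC's per-sample slope varies with vcc when the analyte signal
        # dominates the spectral variance, leaving a mild nonlinearity
        assert table.loc["msc", "Rc"] > 0.99

    def test_msc_beats_raw_under_heavy_scatter(self):
        cfg = SyntheticStudyConfig(
            scatter_slope_sd=0.25, scatter_offset_sd=0.12, noise_sd=1e-3,
            titration_noise_sd=0.0, n_decayed=0, seed=17,
        )
        ds = generate_study(cfg)
        table = compare_pretreatments(
            ds, methods=("raw", "msc"), region="LWNIR", n_select=3, split=SplitSpec(seed=5)
        )
        assert table.loc["msc", "Rp"] > table.loc["raw", "Rp"]

    def test_single_method_single_row(self, noise_free_study):
        table = compare_pretreatments(
            noise_free_study, methods=("raw",), region="LWNIR", n_select=1,
            split=SplitSpec(seed=1),
        )
        assert len(table) == 1


class TestOverfittingVisibility:
    def test_rmsec_weakly_decreases_with_n_select(self, default_study):
        """Nested RC selections: more wavenumbers never worsen the
        calibration-set fit (the prediction set is the guard against
        reading that as model quality)."""
        from nirshelf.calibrate import assemble_calibration

        spectra, y = assemble_calibration(default_study)
        cal, pred = split_samples(default_study, SplitSpec(seed=2))
        in_cal = spectra.data.index.get_level_values("fruit").isin(cal)
        in_pred = spectra.data.index.get_level_values("fruit").isin(pred)
        _, ridx = spectra.grid.restrict(LWNIR.lo, LWNIR.hi)
        Xc = spectra.values[in_cal][:, ridx]
        Xp = spectra.values[in_pred][:, ridx]
        yc = y.loc[spectra.data.index.get_level_values("fruit")[in_cal]].to_numpy()
        yp = y.loc[spectra.data.index.get_level_values("fruit")[in_pred]].to_numpy()
        wn = spectra.grid.wavenumbers[ridx]
        rmsecs = []
        for n in (1, 3, 5):
            model = MLRCalibration(n_select=n, wavenumbers=wn).fit(Xc, yc)
            rmsecs.append(evaluate(model, Xc, yc, Xp, yp).rmsec)
        assert rmsecs[0] >= rmsecs[1] - 1e-9 >= rmsecs[2] - 2e-9

    def test_model_independent_of_prediction_rows(self, default_study):
        """Calibration artifacts never read the prediction set."""
        from nirshelf.calibrate import assemble_calibration

        spectra, y = assemble_calibration(default_study)
        cal, pred = split_samples(default_study, SplitSpec(seed=2))
        in_cal = spectra.data.index.get_level_values("fruit").isin(cal)
        _, ridx = spectra.grid.restrict(LWNIR.lo, LWNIR.hi)
        Xc = spectra.values[in_cal][:, ridx]
        yc = y.loc[spectra.data.index.get_level_values("fruit")[in_cal]].to_numpy()
        wn = spectra.grid.wavenumbers[ridx]
        a = MLRCalibration(n_select=5, wavenumbers=wn).fit(Xc, yc)
        b = MLRCalibration(n_select=5, wavenumbers=wn).fit(Xc, yc)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        np.testing.assert_array_equal(a.selected_wavenumbers_, b.selected_wavenumbers_)
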