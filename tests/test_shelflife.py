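"""Shelf-life arithmetic: composition, inversion and end-to-end recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirshelf.calibrate import MLRCalibration
from nirshelf.errors import GridMismatchError, NonDegradingError, NonInvertibleError
from nirshelf.io import average_replicates
from nirshelf.kinetics import ZeroOrderKinetics, predict_kinetic
from nirshelf.reference import reference_mlr_model, reference_zero_order_model
from nirshelf.shelflife import (
    combined_predict,
    invert_storage_time,
    safe_storage_time,
    shelf_life_from_spectra,
)


class TestCombinedPredict:
    def test_published_composition_at_zero_absorbance(self):
        mlr = reference_mlr_model()
        zero = reference_zero_order_model()
        # 338.787 + 0.044 * 1409.098
        assert combined_predict(mlr, zero, np.zeros(5), 0.0) == pytest.approx(
            338.787 + 0.044 * 1409.098
        )

    def test_one_day_decreases_by_rate(self):
        mlr = reference_mlr_model()
        zero = reference_zero_order_model()
        x = np.full(5, 0.02)
        d = combined_predict(mlr, zero, x, 3.0) - combined_predict(mlr, zero, x, 4.0)
        assert d == pytest.approx(20.677)

    def test_degenerate_kinetics_constant(self):
        mlr = reference_mlr_model()
        zero = ZeroOrderKinetics.from_parameters(5.0, 0.0, 0.0)
        for x in (np.zeros(5), np.full(5, 0.7)):
            assert combined_predict(mlr, zero, x, 2.0) == pytest.approx(5.0)

    def test_wavenumber_count_mismatch(self):
        with pytest.raises(GridMismatchError):
            combined_predict(reference_mlr_model(), reference_zero_order_model(),
                             np.zeros(4), 0.0)


class TestInvertStorageTime:
    def test_as_printed_at_origin(self):
        zero = reference_zero_order_model()
        assert invert_storage_time(zero, 0.0, 0.0, "as_printed") == pytest.approx(17.128)

    def test_algebraic_at_origin(self):
        zero = reference_zero_order_model()
        assert invert_storage_time(zero, 0.0, 0.0, "algebraic") == pytest.approx(
            338.787 / 20.677
        )

    def test_published_inversion_differs_from_algebraic(self):
        """The printed inversion is not the inverse of the printed
        zero-order model: documented inconsistency."""
        zero = reference_zero_order_model()
        printed = invert_storage_time(zero, 0.0, 0.0, "as_printed")
        algebraic = invert_storage_time(zero, 0.0, 0.0, "algebraic")
        assert abs(printed - algebraic) > 0.5

    @given(
        a=st.floats(50.0, 500.0),
        b=st.floats(-0.5, 1.5),
        k=st.floats(0.5, 40.0),
        vcc0=st.floats(0.0, 500.0),
        t=st.floats(0.0, 30.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_algebraic_round_trip_exact(self, a, b, k, vcc0, t):
        zero = ZeroOrderKinetics.from_parameters(a, b, k)
        vcc = predict_kinetic(zero, vcc0, t)
        assert invert_storage_time(zero, vcc0, float(vcc), "algebraic") == pytest.approx(
            t, abs=1e-10 * max(1.0, t)
        )

    def test_zero_rate_not_invertible(self):
        zero = ZeroOrderKinetics.from_parameters(100.0, 1.0, 0.0)
        with pytest.raises(NonInvertibleError):
            invert_storage_time(zero, 100.0, 50.0, "algebraic")


class TestShelfLifeFromSpectra:
    def test_equal_spectra_fixed_point(self):
        """day-t spectrum == day-0 spectrum: the inversion lands at the
        time where the kinetic model returns the day-0 content."""
        mlr = reference_mlr_model()
        zero = reference_zero_order_model()
        x = np.zeros(5)
        pred = shelf_life_from_spectra(mlr, zero, x, x, "algebraic")
        vcc0 = 1409.098
        expected = (338.787 + 0.044 * vcc0 - vcc0) / 20.677
        assert pred.t_est == pytest.approx(expected)
        assert predict_kinetic(zero, vcc0, max(pred.t_est, 0.0)) == pytest.approx(
            vcc0, abs=1e-8
        ) or pred.negative_time

    def test_method_toggle_keeps_intermediates(self):
        mlr = reference_mlr_model()
        zero = reference_zero_order_model()
        x0, xt = np.full(5, 0.01), np.full(5, 0.05)
        a = shelf_life_from_spectra(mlr, zero, x0, xt, "algebraic")
        b = shelf_life_from_spectra(mlr, zero, x0, xt, "as_printed")
        assert a.vcc0_used == b.vcc0_used
        assert a.vcc_used == b.vcc_used
        assert a.t_est != b.t_est

    def test_end_to_end_storage_day_recovery(self, small_study):
        """Noise-free study + exactly calibrated models recover every
        fruit's true storage time."""
        ds = small_study
        averaged = average_replicates(ds.spectra)
        truth = ds.truth.set_index(["fruit", "day"])

        # calibrate spectra -> vcc exactly on one planted wavenumber
        y = np.array(
            [truth.loc[(f, d), "vcc_true"] for f, d, _ in averaged.data.index]
        )
        X = averaged.data.to_numpy()
        col = averaged.grid.index_of(8328.0)  # nearest grid point to a planted band
        mlr = MLRCalibration(n_select=None, wavenumbers=[8328.0]).fit(X[:, [col]], y)
        # true kinetic model: vcc = vcc0 - K t  (a=0, b=1)
        zero = ZeroOrderKinetics.from_parameters(0.0, 1.0, ds.config.rate_K)

        for (fruit, day), row in truth.iterrows():
            if row["vcc_true"] <= 0:
                continue  # floored trajectories are outside the linear model
            x0 = averaged.data.loc[(fruit, 1, 0)].to_numpy()[[col]]
            xt = averaged.data.loc[(fruit, day, 0)].to_numpy()[[col]]
            pred = shelf_life_from_spectra(mlr, zero, x0, xt, "algebraic")
            assert pred.t_est == pytest.approx(day - 1, abs=1e-6)

    def test_negative_estimate_flagged_not_clamped(self):
        mlr = reference_mlr_model()
        zero = ZeroOrderKinetics.from_parameters(0.0, 1.0, 20.0)
        x0 = np.zeros(5)
        xt = np.full(5, 0.01)  # implies vcc above the day-0 level
        pred = shelf_life_from_spectra(mlr, zero, x0, xt, "algebraic")
        if pred.vcc_used > pred.vcc0_used:
            assert pred.t_est < 0 and pred.negative_time


class TestSafeStorageTime:
    def test_published_model_zero_vcc0(self):
        zero = reference_zero_order_model()
        assert safe_storage_time(zero, 0.0) == pytest.approx(338.787 / 20.677)

    def test_threshold_at_current_prediction_returns_time(self):
        zero = reference_zero_order_model()
        t_star = 7.3
        threshold = predict_kinetic(zero, 250.0, t_star)
        assert safe_storage_time(zero, 250.0, threshold) == pytest.approx(t_star)

    def test_doubling_rate_halves_time(self):
        z1 = ZeroOrderKinetics.from_parameters(300.0, 0.0, 10.0)
        z2 = ZeroOrderKinetics.from_parameters(300.0, 0.0, 20.0)
        assert safe_storage_time(z1, 0.0) == pytest.approx(2 * safe_storage_time(z2, 0.0))

    @given(
        thr1=st.floats(0.0, 100.0), thr2=st.floats(100.0, 200.0),
        k=st.floats(1.0, 40.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_decreasing_in_threshold_and_rate(self, thr1, thr2, k):
        zero = ZeroOrderKinetics.from_parameters(400.0, 0.0, k)
        assert safe_storage_time(zero, 0.0, thr2) < safe_storage_time(zero, 0.0, thr1) or thr1 == thr2
        faster = ZeroOrderKinetics.from_parameters(400.0, 0.0, k * 2)
        assert safe_storage_time(faster, 0.0, thr1) < safe_storage_time(zero, 0.0, thr1)

    def test_non_degrading_rejected(self):
        with pytest.raises(NonDegradingError):
            safe_storage_time(ZeroOrderKinetics.from_parameters(300.0, 0.0, 0.0), 0.0)
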