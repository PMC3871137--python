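"""Shelf-life estimation from NIR spectra and degradation kinetics.

Composing the MLR calibration (spectra -> vitamin C) with the
zero-order degradation model (vitamin C vs storage time) gives three
operations:

* :func:`combined_predict` — vitamin C after t days of storage, from a
  day-0 spectrum alone;
* :func:`invert_storage_time` — elapsed storage time from the initial
  and current vitamin C contents;
* :func:`safe_storage_time` — the time at which the modelled content
  crosses a quality threshold (default 0 mg/100 g, the conventional
  end-of-shelf-life criterion for this fruit).

The published storage-time inversion disagrees with the algebraic
inverse of the published zero-order model (intercept 17.128 vs
338.787/20.677 ~ 16.385 at VCC0 = VCC = 0, and the VCC0 term changes
sign).  Both readings are implemented behind an explicit ``method``
flag, default ``"algebraic"``; predictions record which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import MLRCalibration, predict_vcc
from .errors import DomainError, GridMismatchError, NonDegradingError, NonInvertibleError
from .kinetics import ZeroOrderKinetics
from .reference import STORAGE_TIME_INVERSION

__all__ = [
    "ShelfLifePrediction",
    "combined_predict",
    "invert_storage_time",
    "shelf_life_from_spectra",
    "safe_storage_time",
]

METHODS = ("algebraic", "as_printed")


@dataclass
class ShelfLifePrediction:
    """Storage-time estimate with its intermediate quantities."""

    t_est: float  # days
    method: str
    vcc0_used: float  # mg/100 g, from the day-0 spectrum
    vcc_used: float  # mg/100 g, from the day-t spectrum
    negative_time: bool = False  # spectra imply vcc above the day-0 level
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "t_est_days": self.t_est,
            "method": self.method,
            "vcc0_mg_per_100g": self.vcc0_used,
            "vcc_mg_per_100g": self.vcc_used,
            "negative_time": self.negative_time,
            **self.notes,
        }


def _check_method(method: str) -> str:
    method = method.replace("-", "_").lower()
    if method not in METHODS:
        raise DomainError(f"unknown inversion method {method!r}; expected {METHODS}")
    return method


def _selected_absorbances(mlr: MLRCalibration, absorbances) -> np.ndarray:
    a = np.asarray(absorbances, dtype=float).ravel()
    if a.size != np.asarray(mlr.coef_).size:
        raise GridMismatchError(
            f"expected {np.asarray(mlr.coef_).size} absorbances "
            f"(one per selected wavenumber), got {a.size}"
        )
    return a


def combined_predict(
    mlr: MLRCalibration,
    zero: ZeroOrderKinetics,
    day0_absorbances,
    t: float,
) -> float:
    """Vitamin C after t days, straight from the day-0 spectrum.

    Evaluates ``a + b * MLR(day0) - K t``: the zero-order model with its
    initial content supplied by the spectroscopic calibration.
    """
    if t < 0:
        raise DomainError("storage time must be non-negative")
    x = _selected_absorbances(mlr, day0_absorbances)
    vcc0 = float(predict_vcc(mlr, x)[0])
    return zero.intercept_ + zero.vcc0_coef_ * vcc0 - zero.rate_ * float(t)


def invert_storage_time(
    zero: ZeroOrderKinetics,
    vcc0: float,
    vcc: float,
    method: str = "algebraic",
) -> float:
    """Storage time from initial and current vitamin C contents.

    ``algebraic`` inverts the zero-order model exactly:
    ``t = (a + b * vcc0 - vcc) / K``.  ``as_printed`` evaluates the
    published inversion coefficients verbatim
    (``t = 17.128 - 0.002 vcc0 - 0.046 vcc``), which is *not* the
    algebraic inverse of the published zero-order model.
    """
    method = _check_method(method)
    if method == "as_printed":
        c, b0, b1 = STORAGE_TIME_INVERSION
        return c + b0 * vcc0 + b1 * vcc
    if zero.rate_ == 0:
        raise NonInvertibleError("zero-order rate K = 0: model is not invertible in t")
    return (zero.intercept_ + zero.vcc0_coef_ * vcc0 - vcc) / zero.rate_


def shelf_life_from_spectra(
    mlr: MLRCalibration,
    zero: ZeroOrderKinetics,
    day0_absorbances,
    dayt_absorbances,
    method: str = "algebraic",
) -> ShelfLifePrediction:
    """Spectra-only storage-time estimate.

    The day-0 and day-t spectra are converted to vitamin C contents by
    the MLR calibration; the kinetic model is then inverted for the
    elapsed time.  A negative estimate (day-t spectrum implying more
    vitamin C than day 0) is flagged, not clamped.
    """
    method = _check_method(method)
    x0 = _selected_absorbances(mlr, day0_absorbances)
    xt = _selected_absorbances(mlr, dayt_absorbances)
    vcc0 = float(predict_vcc(mlr, x0)[0])
    vcc = float(predict_vcc(mlr, xt)[0])
    t_est = invert_storage_time(zero, vcc0, vcc, method)
    return ShelfLifePrediction(
        t_est=float(t_est),
        method=method,
        vcc0_used=vcc0,
        vcc_used=vcc,
        negative_time=bool(t_est < 0),
    )


def safe_storage_time(
    zero: ZeroOrderKinetics,
    vcc0: float,
    threshold: float = 0.0,
) -> float:
    """Days until the modelled vitamin C crosses ``threshold``.

    ``t = (a + b * vcc0 - threshold) / K``; requires a degrading system
    (K > 0).  The default threshold of 0 mg/100 g is the conventional
    end point for this quality factor, exposed because it is a modelling
    convention rather than a safety standard.
    """
    if zero.rate_ <= 0:
        raise NonDegradingError("safe storage time requires a positive decay rate K")
    return (zero.intercept_ + zero.vcc0_coef_ * vcc0 - threshold) / zero.rate_
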