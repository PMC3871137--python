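"""Degradation kinetics of vitamin C during storage.

Food-quality losses are conventionally described by zero-order
(``C = C0 - K t``, linear) or first-order (``C = C0 * exp(-K t)``,
exponential) reaction models, where C is the quality factor (here
vitamin C, mg/100 g), t the storage time in days and K the rate
constant.

Because sampling is destructive (each fruit is titrated once), the
zero-order model is fitted in the three-parameter regression form

    VCC = a + b * VCC0 - K * t

where VCC0 is the fruit's spectroscopically predicted day-0 content.
The textbook two-parameter form is available as the ``fixed_vcc0``
special case (a = 0, b = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    CollinearityError,
    ConfigError,
    DomainError,
    FitFailureError,
    ValidationError,
)

__all__ = [
    "ZeroOrderKinetics",
    "FirstOrderKinetics",
    "KineticsComparison",
    "fit_zero_order",
    "fit_first_order",
    "compare_kinetics",
    "predict_kinetic",
]


def _as_xy(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


class ZeroOrderKinetics(BaseEstimator, RegressorMixin):
    """Zero-order (linear) degradation model fitted by OLS.

    ``fit`` expects ``X`` with two columns ``(vcc0, t)`` and the
    observed contents ``y``.  With ``fixed_vcc0=True`` the model is the
    textbook ``C = C0 - K t`` (intercept 0, vcc0 coefficient 1) and only
    K is estimated.

    Fitted attributes: ``intercept_`` (a), ``vcc0_coef_`` (b), ``rate_``
    (K, mg/100 g/day, the negated t-coefficient), ``se_rate_``,
    ``ci_rate_`` (95 % t-interval for K) and ``ci_mean_`` (95 %
    interval for the mean fitted value).
    """

    def __init__(self, fixed_vcc0: bool = False):
        self.fixed_vcc0 = fixed_vcc0

    def fit(self, X, y):
        X = _as_xy(X)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 2:
            raise ConfigError("X must have two columns: (vcc0, t)")
        if X.shape[0] < 4:
            raise ValidationError("need at least 4 observations")
        vcc0, t = X[:, 0], X[:, 1]
        if np.ptp(t) == 0:
            raise ValidationError("storage times are all equal; K is unidentifiable")

        if self.fixed_vcc0:
            # (vcc0 - y) = K t through the origin
            denom = float(t @ t)
            k = float(t @ (vcc0 - y)) / denom
            resid = y - (vcc0 - k * t)
            dof = len(y) - 1
            s2 = float(resid @ resid) / dof
            se_k = np.sqrt(s2 / denom)
            beta = np.array([0.0, 1.0, -k])
            fitted = vcc0 - k * t
        else:
            design = np.column_stack([np.ones_like(y), vcc0, t])
            if np.linalg.matrix_rank(design) < 3:
                raise CollinearityError("vcc0 and t columns are collinear")
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            fitted = design @ beta
            resid = y - fitted
            dof = len(y) - 3
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(design.T @ design)
            se_k = float(np.sqrt(cov[2, 2]))
            k = -float(beta[2])

        tcrit = stats.t.ppf(0.975, dof)
        self.intercept_ = float(beta[0])
        self.vcc0_coef_ = float(beta[1])
        self.rate_ = float(k)
        self.se_rate_ = float(se_k)
        self.ci_rate_ = (k - tcrit * se_k, k + tcrit * se_k)
        half = tcrit * np.sqrt(s2 / len(y))
        self.ci_mean_ = (float(fitted.mean() - half), float(fitted.mean() + half))
        self.resid_std_ = float(np.sqrt(s2))
        self.n_obs_ = len(y)
        if k <= 0:
            warnings.warn("estimated rate K <= 0: system does not degrade", stacklevel=2)
        return self

    @classmethod
    def from_parameters(cls, intercept, vcc0_coef, rate, ci_mean=(np.nan, np.nan)):
        """Build an already-parameterised model (e.g. a published one)."""
        model = cls()
        model.intercept_ = float(intercept)
        model.vcc0_coef_ = float(vcc0_coef)
        model.rate_ = float(rate)
        model.se_rate_ = np.nan
        model.ci_rate_ = (np.nan, np.nan)
        model.ci_mean_ = tuple(ci_mean)
        model.resid_std_ = np.nan
        model.n_obs_ = 0
        return model

    def predict(self, X) -> np.ndarray:
        """a + b*vcc0 - K*t; deliberately not floored at zero so that the
        linear model can be inverted for storage time."""
        check_is_fitted(self, "rate_")
        X = _as_xy(X)
        return self.intercept_ + self.vcc0_coef_ * X[:, 0] - self.rate_ * X[:, 1]

    def to_dict(self) -> dict:
        check_is_fitted(self, "rate_")
        return {
            "form": "zero",
            "intercept": self.intercept_,
            "vcc0_coef": self.vcc0_coef_,
            "rate_per_day": self.rate_,
            "se_rate": self.se_rate_,
            "ci_mean_low": self.ci_mean_[0],
            "ci_mean_high": self.ci_mean_[1],
            "n_obs": self.n_obs_,
        }


class FirstOrderKinetics(BaseEstimator, RegressorMixin):
    """First-order (exponential) degradation fitted by nonlinear LS.

    ``C0 * exp(-K t)`` is fitted by Levenberg-Marquardt, initialised
    from a log-linear regression on the strictly positive observations
    (log-linearisation is biased under additive noise, so it serves only
    as a starting point).  Fitted attributes: ``c0_``, ``rate_``
    (1/day), ``se_rate_``, ``converged_``.
    """

    def __init__(self, max_iterations: int = 10_000):
        self.max_iterations = max_iterations

    def fit(self, X, y):
        t = _as_xy(X)[:, 0]
        y = np.asarray(y, dtype=float)
        if t.size < 3:
            raise ValidationError("need at least 3 observations")
        pos = y > 0
        if not pos.any():
            raise ValidationError("all observations non-positive: cannot fit exponential")
        slope, logc0 = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(logc0)), float(max(-slope, 0.0)))

        def f(tt, c0, k):
            return c0 * np.exp(-k * tt)

        try:
            popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=self.max_iterations)
        except RuntimeError as exc:
            raise FitFailureError(f"first-order fit did not converge: {exc}") from exc
        self.c0_ = float(popt[0])
        self.rate_ = float(popt[1])
        self.se_rate_ = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
        self.converged_ = True
        resid = y - f(t, *popt)
        self.resid_std_ = float(np.sqrt(np.mean(resid**2)))
        self.n_obs_ = int(t.size)
        return self

    @classmethod
    def from_parameters(cls, c0, rate):
        model = cls()
        model.c0_ = float(c0)
        model.rate_ = float(rate)
        model.se_rate_ = np.nan
        model.converged_ = True
        model.resid_std_ = np.nan
        model.n_obs_ = 0
        return model

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rate_")
        t = _as_xy(X)[:, 0]
        return self.c0_ * np.exp(-self.rate_ * t)

    def to_dict(self) -> dict:
        check_is_fitted(self, "rate_")
        return {
            "form": "first",
            "c0": self.c0_,
            "rate_per_day": self.rate_,
            "se_rate": self.se_rate_,
            "n_obs": self.n_obs_,
        }


@dataclass
class KineticsComparison:
    """Side-by-side goodness of fit of the two kinetic forms."""

    r_zero: float
    rmsec_zero: float
    r_first: float
    rmsec_first: float
    chosen: str  # "zero" | "first"

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "zero_order": {"form": "linear", "R": self.r_zero, "RMSEC": self.rmsec_zero},
                "first_order": {"form": "exponent", "R": self.r_first, "RMSEC": self.rmsec_first},
            }
        )


def fit_zero_order(vcc, vcc0, t, *, fixed_vcc0: bool = False) -> ZeroOrderKinetics:
    """OLS fit of ``vcc ~ a + b*vcc0 - K*t``."""
    X = np.column_stack([np.asarray(vcc0, float), np.asarray(t, float)])
    return ZeroOrderKinetics(fixed_vcc0=fixed_vcc0).fit(X, np.asarray(vcc, float))


def fit_first_order(vcc, t, **kwargs) -> FirstOrderKinetics:
    """Nonlinear LS fit of ``vcc ~ C0 * exp(-K t)``."""
    return FirstOrderKinetics(**kwargs).fit(np.asarray(t, float), np.asarray(vcc, float))


def _r_rmse(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(obs) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return r, float(np.sqrt(np.mean((pred - obs) ** 2)))


def compare_kinetics(
    zero: ZeroOrderKinetics,
    first: FirstOrderKinetics,
    vcc,
    vcc0,
    t,
) -> KineticsComparison:
    """Correlation/RMSEC of both models on shared observations.

    The chosen model is the one with the larger correlation; exact ties
    go to the zero-order (simpler) form.
    """
    vcc = np.asarray(vcc, float)
    Xz = np.column_stack([np.asarray(vcc0, float), np.asarray(t, float)])
    rz, ez = _r_rmse(zero.predict(Xz), vcc)
    rf, ef = _r_rmse(first.predict(np.asarray(t, float)), vcc)
    chosen = "zero" if (np.isnan(rf) or rz >= rf) else "first"
    return KineticsComparison(rz, ez, rf, ef, chosen)


def predict_kinetic(model, vcc0: float, t) -> np.ndarray | float:
    """Evaluate a kinetic model's closed form at storage time(s) t >= 0.

    The zero-order output is intentionally not floored at zero: the
    shelf-life inversion relies on the linear extrapolation through
    zero.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("storage time must be non-negative")
    if isinstance(model, ZeroOrderKinetics):
        out = model.intercept_ + model.vcc0_coef_ * vcc0 - model.rate_ * t_arr
    elif isinstance(model, FirstOrderKinetics):
        out = model.c0_ * np.exp(-model.rate_ * t_arr)
    else:
        raise ConfigError(f"unknown kinetic model type {type(model).__name__}")
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
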