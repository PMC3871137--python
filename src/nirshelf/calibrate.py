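"""MLR calibration of vitamin C on selected wavenumbers.

The calibration chain is: hold-out split -> pretreatment -> region
restriction -> regression-coefficient (RC) wavelength selection ->
ordinary least-squares MLR -> evaluation (Rc/RMSEC on the calibration
set, Rp/RMSEP on the prediction set).

RC selection computes a full-spectrum coefficient vector by
ridge-stabilised least squares (the ridge penalty only regularises the
heavily collinear full-spectrum problem; the final model is plain OLS on
the selected columns), then keeps the ``n_select`` largest local maxima
of the absolute coefficient trace.  Ties are broken toward the lower
wavenumber, and the selection is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import (
    CollinearityError,
    ConfigError,
    GridMismatchError,
    SelectionError,
    SplitError,
)
from .grid import SpectralRegion, get_region
from .io import SpectraSet, average_replicates
from .pretreat import PRETREATMENT_ORDER, make_pretreatment

__all__ = [
    "SplitSpec",
    "CalibrationMetrics",
    "MLRCalibration",
    "split_samples",
    "select_wavenumbers_rc",
    "fit_mlr",
    "predict_vcc",
    "evaluate",
    "compare_pretreatments",
    "assemble_calibration",
]


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out split: sizes, decay exclusion, and the RNG seed."""

    n_calibration: int = 50
    n_prediction: int = 17
    exclude_decayed: bool = True
    seed: int = 0


@dataclass
class CalibrationMetrics:
    """Calibration/prediction figures of merit for one model."""

    n_selected: int
    rc: float
    rmsec: float
    rp: float
    rmsep: float
    undefined_correlation: bool = False
    method: str | None = None

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "N": self.n_selected,
            "Rc": self.rc,
            "RMSEC": self.rmsec,
            "Rp": self.rp,
            "RMSEP": self.rmsep,
        }


def split_samples(dataset, spec: SplitSpec = SplitSpec()) -> tuple[list[str], list[str]]:
    """Random disjoint calibration/prediction fruit-id sets.

    Decayed fruits are excluded before drawing when
    ``spec.exclude_decayed`` is set.  Uniformly random but fully
    reproducible for a given seed.
    """
    manifest = dataset.manifest
    ids = manifest["fruit"].tolist()
    if spec.exclude_decayed:
        ids = manifest.loc[~manifest["decayed"].astype(bool), "fruit"].tolist()
    ids = sorted(ids)
    need = spec.n_calibration + spec.n_prediction
    if need > len(ids):
        raise SplitError(
            f"need {need} samples for a {spec.n_calibration}/{spec.n_prediction} "
            f"split but only {len(ids)} are available"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(ids))
    cal = sorted(ids[i] for i in perm[: spec.n_calibration])
    pred = sorted(ids[i] for i in perm[spec.n_calibration : need])
    return cal, pred


def _rc_vector(X: np.ndarray, y: np.ndarray, alpha_scale: float) -> np.ndarray:
    """Ridge-stabilised full-spectrum regression coefficients."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    gram = Xc.T @ Xc
    lam = alpha_scale * np.trace(gram) / X.shape[1]
    if lam <= 0:
        lam = alpha_scale  # all-constant X: any solution is zero anyway
    return np.linalg.solve(gram + lam * np.eye(X.shape[1]), Xc.T @ yc)


def _local_maxima(trace: np.ndarray) -> np.ndarray:
    """Interior indices where the trace peaks (plateau-aware, no endpoints)."""
    left = trace[1:-1] >= trace[:-2]
    right = trace[1:-1] >= trace[2:]
    strict = (trace[1:-1] > trace[:-2]) | (trace[1:-1] > trace[2:])
    return np.flatnonzero(left & right & strict) + 1


def select_wavenumbers_rc(
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray,
    n_select: int,
    alpha_scale: float = 1e-3,
) -> list[float]:
    """Pick the ``n_select`` strongest |RC| local maxima.

    Returns wavenumbers sorted descending.  Raises
    :class:`SelectionError` when fewer maxima exist than requested.
    """
    if n_select < 1:
        raise ConfigError("n_select must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if X.shape[1] != wavenumbers.size:
        raise GridMismatchError("X columns and wavenumber axis differ in length")
    rc = np.abs(_rc_vector(X, y, alpha_scale))
    peaks = _local_maxima(rc)
    if peaks.size < n_select:
        raise SelectionError(
            f"only {peaks.size} |RC| local maxima found, {n_select} requested"
        )
    # rank by |RC| descending; near-exact ties (1e-10 relative) go to the
    # lower wavenumber
    scale = rc[peaks].max() or 1.0
    order = sorted(peaks, key=lambda i: (-round(rc[i] / scale * 1e10), wavenumbers[i]))
    chosen = sorted(order[:n_select], key=lambda i: -wavenumbers[i])
    return [float(wavenumbers[i]) for i in chosen]


def _check_full_rank(design: np.ndarray, wavenumbers: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    p = design.shape[1]
    if rank < p:
        # identify the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(design, mode="economic", pivoting=True)
        dep = piv[rank:]
        names = ["intercept" if j == 0 else f"{wavenumbers[j - 1]:g}" for j in sorted(dep)]
        raise CollinearityError(
            f"design matrix rank {rank} < {p}; dependent columns: {', '.join(names)}"
        )


class MLRCalibration(BaseEstimator, RegressorMixin):
    """RC wavelength selection + ordinary least-squares MLR.

    Parameters
    ----------
    n_select : int or None
        Number of wavenumbers to keep by RC selection.  ``None`` skips
        selection and regresses on all supplied columns (used when the
        columns were already selected).
    alpha_scale : float
        Ridge penalty for the full-spectrum RC vector, as a fraction of
        ``trace(X'X)/p``.
    wavenumbers : array-like or None
        Wavenumber axis of the training columns; defaults to column
        indices when omitted.

    Fitted attributes
    -----------------
    intercept_, coef_ : OLS parameters (mg/100 g; mg/100 g per AU).
    selected_wavenumbers_, selected_idx_ : the kept columns, descending.
    ci_mean_ : 95 % t-interval for the mean of the fitted values.
    """

    def __init__(
        self,
        n_select: int | None = 5,
        alpha_scale: float = 1e-3,
        wavenumbers=None,
    ):
        self.n_select = n_select
        self.alpha_scale = alpha_scale
        self.wavenumbers = wavenumbers

    def _wn(self, n_cols: int) -> np.ndarray:
        if self.wavenumbers is None:
            return np.arange(n_cols, dtype=float)[::-1]  # pseudo-descending axis
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.size != n_cols:
            raise GridMismatchError("wavenumbers length mismatches X columns")
        return wn

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        wn = self._wn(X.shape[1])
        if self.n_select is None:
            idx = np.arange(X.shape[1])
        else:
            selected = select_wavenumbers_rc(X, y, wn, self.n_select, self.alpha_scale)
            idx = np.array([int(np.argmin(np.abs(wn - w))) for w in selected])
        Xsel = X[:, idx]
        n, p = Xsel.shape
        if n <= p + 1:
            raise ConfigError(f"need more than {p + 1} samples to fit {p} coefficients")
        design = np.column_stack([np.ones(n), Xsel])
        _check_full_rank(design, wn[idx])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ beta
        resid = y - fitted
        dof = n - p - 1
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
        half = tcrit * np.sqrt(s2 / n)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.selected_idx_ = idx
        self.selected_wavenumbers_ = wn[idx]
        self.resid_std_ = float(np.sqrt(s2))
        self.ci_mean_ = (float(fitted.mean() - half), float(fitted.mean() + half))
        self.n_features_in_ = X.shape[1]
        self.n_obs_ = n
        return self

    @classmethod
    def from_coefficients(cls, intercept, coefficients, wavenumbers) -> "MLRCalibration":
        """Build an already-parameterised model (e.g. a published one)."""
        coefficients = np.asarray(coefficients, dtype=float)
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        if coefficients.size != wavenumbers.size:
            raise GridMismatchError("one coefficient per wavenumber required")
        model = cls(n_select=coefficients.size, wavenumbers=None)
        model.intercept_ = float(intercept)
        model.coef_ = coefficients
        model.selected_wavenumbers_ = wavenumbers
        model.selected_idx_ = np.arange(coefficients.size)
        model.n_features_in_ = coefficients.size
        model.ci_mean_ = (np.nan, np.nan)
        model.resid_std_ = np.nan
        model.n_obs_ = 0
        return model

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(np.atleast_2d(X))
        if X.shape[1] == self.coef_.size:
            Xsel = X  # already the selected columns
        elif X.shape[1] == self.n_features_in_:
            Xsel = X[:, self.selected_idx_]
        else:
            raise GridMismatchError(
                f"expected {self.coef_.size} selected or {self.n_features_in_} "
                f"full columns, got {X.shape[1]}"
            )
        return self.intercept_ + Xsel @ self.coef_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "intercept": self.intercept_,
            "coefficients": self.coef_.tolist(),
            "wavenumbers": np.asarray(self.selected_wavenumbers_).tolist(),
            "ci_mean_low": self.ci_mean_[0],
            "ci_mean_high": self.ci_mean_[1],
            "n_obs": self.n_obs_,
        }


def fit_mlr(X_selected, y, wavenumbers=None) -> MLRCalibration:
    """OLS on already-selected absorbance columns."""
    model = MLRCalibration(n_select=None, wavenumbers=wavenumbers)
    return model.fit(X_selected, y)


def predict_vcc(model: MLRCalibration, spectra) -> np.ndarray:
    """Predict vitamin C (mg/100 g) from spectra.

    ``spectra`` may be a :class:`SpectraSet` (the model's selected
    wavenumbers are looked up on its grid) or a plain array of selected
    absorbances.
    """
    if isinstance(spectra, SpectraSet):
        cols = [spectra.grid.index_of(w) for w in np.asarray(model.selected_wavenumbers_)]
        Xsel = spectra.values[:, cols]
        return model.intercept_ + Xsel @ model.coef_
    return model.predict(np.atleast_2d(np.asarray(spectra, dtype=float)))


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, True
    return float(np.corrcoef(a, b)[0, 1]), False


def evaluate(
    model: MLRCalibration,
    X_cal,
    y_cal,
    X_pred,
    y_pred,
    *,
    method: str | None = None,
    rmse_dof_adjust: bool = False,
) -> CalibrationMetrics:
    """Rc/RMSEC and Rp/RMSEP for one fitted model.

    R is the Pearson correlation between predicted and measured values;
    RMSE uses denominator n (set ``rmse_dof_adjust`` for n - p - 1 on
    the calibration set).  Constant predictions yield an
    ``undefined_correlation`` flag rather than an exception.
    """
    y_cal = np.asarray(y_cal, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    yhat_c = model.predict(X_cal)
    yhat_p = model.predict(X_pred)
    rc, flag_c = _pearson(yhat_c, y_cal)
    rp, flag_p = _pearson(yhat_p, y_pred)
    denom_c = len(y_cal) - model.coef_.size - 1 if rmse_dof_adjust else len(y_cal)
    rmsec = float(np.sqrt(np.sum((yhat_c - y_cal) ** 2) / denom_c))
    rmsep = float(np.sqrt(np.mean((yhat_p - y_pred) ** 2)))
    return CalibrationMetrics(
        n_selected=int(model.coef_.size),
        rc=rc,
        rmsec=rmsec,
        rp=rp,
        rmsep=rmsep,
        undefined_correlation=flag_c or flag_p,
        method=method,
    )


#: characteristic-wavenumber counts conventionally used per pretreatment
DEFAULT_N_SELECT = {"raw": 6, "sg": 6, "msc": 6, "d1": 12, "d2": 10}


def assemble_calibration(dataset) -> tuple[SpectraSet, pd.Series]:
    """Per-fruit design: replicate-averaged titration-day spectrum + VCC.

    Each fruit contributes one observation — the spectrum measured on
    the day it was destructively titrated, paired with the titrated
    vitamin C content.
    """
    averaged = average_replicates(dataset.spectra)
    tit = dataset.titrations.set_index("fruit")
    rows, y, index = [], [], []
    for fruit, rec in tit.iterrows():
        day = int(rec["day"])
        rows.append(averaged.data.loc[(fruit, day, 0)].to_numpy())
        y.append(float(rec["vcc"]))
        index.append((fruit, day, 0))
    from .io import make_spectra_set

    spectra = make_spectra_set(averaged.grid, np.vstack(rows), index)
    return spectra, pd.Series(y, index=[f for f, _, _ in index], name="vcc")


def compare_pretreatments(
    dataset,
    methods=PRETREATMENT_ORDER,
    region: str | SpectralRegion = "VNIR",
    n_select: int | dict | None = None,
    split: SplitSpec = SplitSpec(),
) -> pd.DataFrame:
    """Table-style comparison of pretreatment techniques.

    Fits one MLR model per pretreatment on a shared calibration split
    and reports N, Rc, RMSEC, Rp, RMSEP per method, in the conventional
    order (raw, sg, msc, d1, d2).  Set-based pretreatments (MSC) derive
    their reference from the calibration set only.
    """
    spectra, y = assemble_calibration(dataset)
    cal_ids, pred_ids = split_samples(dataset, split)
    region = get_region(region)
    order = {m: i for i, m in enumerate(PRETREATMENT_ORDER)}
    methods = sorted((canonical(m) for m in methods), key=order.__getitem__)

    rows = []
    for method in methods:
        n_sel = n_select
        if isinstance(n_select, dict):
            n_sel = n_select[method]
        if n_sel is None:
            n_sel = DEFAULT_N_SELECT[method]
        transformer = make_pretreatment(method, spacing=spectra.grid.spacing)
        X_cal_full = spectra.data.loc[[(f, d, p) for f, d, p in spectra.data.index if f in set(cal_ids)]]
        X_pred_full = spectra.data.loc[[(f, d, p) for f, d, p in spectra.data.index if f in set(pred_ids)]]
        transformer.fit(X_cal_full.to_numpy())
        Xc = transformer.transform(X_cal_full.to_numpy())
        Xp = transformer.transform(X_pred_full.to_numpy())
        _, ridx = spectra.grid.restrict(region.lo, region.hi)
        wn = spectra.grid.wavenumbers[ridx]
        y_cal = y.loc[[f for f, _, _ in X_cal_full.index]].to_numpy()
        y_pred = y.loc[[f for f, _, _ in X_pred_full.index]].to_numpy()
        model = MLRCalibration(n_select=n_sel, wavenumbers=wn)
        model.fit(Xc[:, ridx], y_cal)
        metrics = evaluate(model, Xc[:, ridx], y_cal, Xp[:, ridx], y_pred, method=method)
        rows.append(metrics.as_row())
    return pd.DataFrame(rows).set_index("method")


def canonical(method: str) -> str:
    from .pretreat import canonical_method

    return canonical_method(method)
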