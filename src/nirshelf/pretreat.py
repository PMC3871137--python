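"""Spectral pretreatment operators.

Two families of scatter/noise correction common in NIR chemometrics:

* :class:`SavitzkyGolay` — local polynomial least-squares smoothing, and
  smoothed first/second derivatives with respect to wavenumber;
* :class:`MultiplicativeScatterCorrection` — per-spectrum affine
  regression against a reference (by default the calibration-set mean)
  that removes multiplicative and additive scatter caused by particle
  size variation in intact fruit tissue.

Both are sklearn transformers operating on sample-by-wavenumber
matrices, so they compose with pipelines; thin functional wrappers
(:func:`savgol`, :func:`msc_fit`, :func:`msc_apply`) cover the
single-spectrum case.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConfigError,
    DegenerateFitError,
    FilterSizeError,
    InsufficientSetError,
)
from .grid import DEFAULT_STEP

#: Pretreatment names in the conventional comparison order.
PRETREATMENT_ORDER = ("raw", "sg", "msc", "d1", "d2")

_ALIASES = {
    "raw": "raw",
    "sg": "sg",
    "sg_smooth": "sg",
    "msc": "msc",
    "d1": "d1",
    "deriv1": "d1",
    "1-der": "d1",
    "d2": "d2",
    "deriv2": "d2",
    "2-der": "d2",
}


def canonical_method(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ConfigError(f"unknown pretreatment {name!r}; expected one of {PRETREATMENT_ORDER}")
    return _ALIASES[key]


class SavitzkyGolay(BaseEstimator, TransformerMixin):
    """Savitzky-Golay smoothing / derivative filter.

    Parameters
    ----------
    half_window : int
        Points on each side of the centre; the filter window is
        ``2 * half_window + 1`` (default 10 -> 21-point window).
    poly_order : int
        Degree of the local polynomial (default 2).
    deriv_order : int
        0 for smoothing, 1/2 for smoothed derivatives with respect to
        wavenumber (units absorbance per cm^-1 etc.).
    spacing : float
        Grid step magnitude in cm^-1 used to scale derivatives.
    descending : bool
        Whether the wavenumber axis decreases along columns (the package
        convention); flips the sign of odd derivatives.
    edge_policy : {"reflect", "shrink"}
        "reflect" mirrors the signal at the edges so output length
        equals input length; "shrink" drops the ``half_window`` edge
        points on each side.
    """

    def __init__(
        self,
        half_window: int = 10,
        poly_order: int = 2,
        deriv_order: int = 0,
        spacing: float = DEFAULT_STEP,
        descending: bool = True,
        edge_policy: str = "reflect",
    ):
        self.half_window = half_window
        self.poly_order = poly_order
        self.deriv_order = deriv_order
        self.spacing = spacing
        self.descending = descending
        self.edge_policy = edge_policy

    @property
    def window_(self) -> int:
        return 2 * self.half_window + 1

    def _validate(self, n_points: int) -> None:
        if not self.window_ > self.poly_order >= self.deriv_order >= 0:
            raise ConfigError(
                f"need window ({self.window_}) > poly_order ({self.poly_order}) "
                f">= deriv_order ({self.deriv_order})"
            )
        if self.edge_policy not in ("reflect", "shrink"):
            raise ConfigError(f"unknown edge_policy {self.edge_policy!r}")
        if n_points < self.window_:
            raise FilterSizeError(
                f"window {self.window_} exceeds spectrum length {n_points}"
            )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self._validate(X.shape[-1])
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._validate(X.shape[-1])
        out = savgol_filter(
            X,
            window_length=self.window_,
            polyorder=self.poly_order,
            deriv=self.deriv_order,
            delta=self.spacing,
            axis=-1,
            mode="mirror",
        )
        if self.descending and self.deriv_order % 2 == 1:
            out = -out
        if self.edge_policy == "shrink":
            out = out[:, self.half_window : -self.half_window]
        return out


class MultiplicativeScatterCorrection(BaseEstimator, TransformerMixin):
    """MSC against the calibration-set mean (or a supplied reference).

    ``fit`` stores the point-wise mean of the training spectra as the
    reference; ``transform`` regresses each spectrum on the reference by
    ordinary least squares, ``x ~ a + b * ref``, and returns
    ``(x - a) / b``.  The reference learned on the calibration set must
    be reused for prediction-set spectra (no information leakage).
    """

    #: slopes below this magnitude are treated as degenerate
    slope_tol = 1e-12

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise InsufficientSetError("supplied reference length mismatches spectra")
        else:
            if X.shape[0] < 2:
                raise InsufficientSetError(
                    "MSC with a mean-of-set reference needs at least two spectra"
                )
            ref = X.mean(axis=0)
        if np.ptp(ref) <= self.slope_tol:
            raise DegenerateFitError("MSC reference spectrum is constant")
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        ref = self.reference_
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        if np.any(np.abs(b) < self.slope_tol):
            i = int(np.argmin(np.abs(b)))
            raise DegenerateFitError(
                f"spectrum {i} is uncorrelated with the MSC reference (slope ~ 0)"
            )
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


class IdentityPretreatment(BaseEstimator, TransformerMixin):
    """No-op pretreatment (the raw-spectra baseline)."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.atleast_2d(X).shape[1]
        return self

    def transform(self, X):
        return np.atleast_2d(np.asarray(X, dtype=float))


def make_pretreatment(
    method: str,
    *,
    half_window: int = 10,
    poly_order: int = 2,
    spacing: float = DEFAULT_STEP,
) -> BaseEstimator:
    """Build the named pretreatment transformer.

    Accepted names (case-insensitive): raw, sg (sg_smooth), msc,
    d1 (deriv1, 1-der), d2 (deriv2, 2-der).
    """
    method = canonical_method(method)
    if method == "raw":
        return IdentityPretreatment()
    if method == "msc":
        return MultiplicativeScatterCorrection()
    deriv = {"sg": 0, "d1": 1, "d2": 2}[method]
    order = max(poly_order, deriv)
    return SavitzkyGolay(
        half_window=half_window, poly_order=order, deriv_order=deriv, spacing=spacing
    )


# ---------------------------------------------------------------- wrappers

def savgol(
    values: np.ndarray,
    half_window: int = 10,
    poly_order: int = 2,
    deriv_order: int = 0,
    spacing: float = DEFAULT_STEP,
    edge_policy: str = "reflect",
) -> np.ndarray:
    """Savitzky-Golay filter for a single spectrum (1-D convenience)."""
    est = SavitzkyGolay(
        half_window=half_window,
        poly_order=poly_order,
        deriv_order=deriv_order,
        spacing=spacing,
        edge_policy=edge_policy,
    )
    return est.transform(np.asarray(values, dtype=float)[None, :])[0]


def msc_fit(spectra: np.ndarray) -> np.ndarray:
    """Point-wise mean of a spectra matrix: the MSC reference."""
    est = MultiplicativeScatterCorrection().fit(spectra)
    return est.reference_


def msc_apply(spectrum: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Correct one spectrum against a given MSC reference."""
    est = MultiplicativeScatterCorrection(reference=reference)
    est.fit(np.asarray(spectrum, dtype=float)[None, :])
    return est.transform(np.asarray(spectrum, dtype=float)[None, :])[0]
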