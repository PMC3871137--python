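"""Published reference models for vitamin C in fresh jujube at 20 degC.

These are the reported calibration and kinetic parameters for 'Lizao'
jujube measured by FT-NIR (12,000-4,000 cm^-1): a five-wavenumber MLR
calibration on the 9,091-4,000 cm^-1 range, zero- and first-order
degradation models, and the printed storage-time inversion.  They serve
as fixed oracles in tests and as ready-made models for the shelf-life
arithmetic; nothing in the pipeline depends on them.

Note that the printed storage-time inversion is *not* the algebraic
inverse of the zero-order model (its intercept and the sign of the
VCC0 term disagree); see :mod:`nirshelf.shelflife` for how both
readings are exposed.
"""

from __future__ import annotations

from .calibrate import MLRCalibration
from .kinetics import FirstOrderKinetics, ZeroOrderKinetics

#: Effective wavenumbers (cm^-1) of the long-wavelength NIR calibration,
#: descending, matching the coefficient order below.
REFERENCE_WAVENUMBERS = (8_330.0, 6_900.0, 5_666.0, 5_150.0, 4_060.0)

REFERENCE_MLR_INTERCEPT = 1409.098
REFERENCE_MLR_COEFFICIENTS = (1586.574, 2145.536, -3501.009, -277.794, 30.116)
REFERENCE_MLR_CI_MEAN = (173.683, 217.234)

#: Zero-order model: VCC = 338.787 + 0.044 VCC0 - 20.677 t
REFERENCE_ZERO_ORDER = (338.787, 0.044, 20.677)
REFERENCE_ZERO_ORDER_CI_MEAN = (150.648, 201.676)

#: First-order model: VCC = 550.58 exp(-0.164 t)
REFERENCE_FIRST_ORDER = (550.58, 0.164)

#: Printed storage-time inversion: t = 17.128 - 0.002 VCC0 - 0.046 VCC
STORAGE_TIME_INVERSION = (17.128, -0.002, -0.046)


def reference_mlr_model() -> MLRCalibration:
    """The published five-wavenumber MLR calibration."""
    return MLRCalibration.from_coefficients(
        REFERENCE_MLR_INTERCEPT, REFERENCE_MLR_COEFFICIENTS, REFERENCE_WAVENUMBERS
    )


def reference_zero_order_model() -> ZeroOrderKinetics:
    """The published zero-order degradation model."""
    a, b, k = REFERENCE_ZERO_ORDER
    return ZeroOrderKinetics.from_parameters(a, b, k, ci_mean=REFERENCE_ZERO_ORDER_CI_MEAN)


def reference_first_order_model() -> FirstOrderKinetics:
    """The published first-order degradation model."""
    c0, k = REFERENCE_FIRST_ORDER
    return FirstOrderKinetics.from_parameters(c0, k)
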