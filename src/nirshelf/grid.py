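"""Wavenumber grids and named NIR spectral regions.

Spectra live on a shared, uniformly spaced wavenumber grid ordered from
high to low wavenumber (the convention of FT-NIR instruments).  The
default grid spans 12,000-4,000 cm^-1 at 8 cm^-1 steps (1001 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError, FormatError

#: Relative tolerance for judging grid spacing uniform.
_SPACING_RTOL = 1e-9

DEFAULT_START = 12_000.0
DEFAULT_STOP = 4_000.0
DEFAULT_STEP = 8.0


@dataclass(frozen=True)
class SpectrumGrid:
    """A strictly descending, uniformly spaced wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise FormatError("grid needs at least two wavenumber points")
        if not np.all(np.isfinite(wn)) or np.any(wn <= 0):
            raise FormatError("wavenumbers must be finite and positive")
        diffs = np.diff(wn)
        if not np.all(diffs < 0):
            raise FormatError("wavenumbers must be strictly descending")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=_SPACING_RTOL, atol=0):
            bad = int(np.argmax(~np.isclose(diffs, step, rtol=_SPACING_RTOL, atol=0)))
            raise FormatError(
                f"non-uniform grid spacing between points {bad} and {bad + 1} "
                f"({wn[bad]:g} -> {wn[bad + 1]:g} cm^-1)"
            )
        object.__setattr__(self, "wavenumbers", wn)

    @classmethod
    def default(cls) -> "SpectrumGrid":
        n = int(round((DEFAULT_START - DEFAULT_STOP) / DEFAULT_STEP)) + 1
        return cls(np.linspace(DEFAULT_START, DEFAULT_STOP, n))

    def __len__(self) -> int:
        return self.wavenumbers.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumGrid):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=0, atol=1e-9
        )

    @property
    def spacing(self) -> float:
        """Magnitude of the grid step in cm^-1."""
        return float(self.wavenumbers[0] - self.wavenumbers[1])

    def index_of(self, wavenumber: float, *, nearest: bool = False) -> int:
        """Index of a wavenumber on the grid.

        With ``nearest=False`` the value must lie on the grid (within
        1e-6 cm^-1); otherwise the closest grid point is returned.
        """
        idx = int(np.argmin(np.abs(self.wavenumbers - wavenumber)))
        if not nearest and abs(self.wavenumbers[idx] - wavenumber) > 1e-6:
            from .errors import GridMismatchError

            raise GridMismatchError(f"wavenumber {wavenumber:g} cm^-1 is not on the grid")
        return idx

    def restrict(self, lo: float, hi: float) -> tuple["SpectrumGrid", np.ndarray]:
        """Sub-grid with lo <= wavenumber <= hi (closed interval).

        Returns the sub-grid and the integer indices into this grid.
        """
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise EmptyRegionError(
                f"region [{lo:g}, {hi:g}] cm^-1 covers fewer than two grid points"
            )
        idx = np.flatnonzero(mask)
        return SpectrumGrid(self.wavenumbers[idx]), idx


@dataclass(frozen=True)
class SpectralRegion:
    """A named closed wavenumber interval [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise FormatError(f"region {self.name}: lo must be < hi")


#: Whole range, and the short-/long-wavelength halves split at 9,091 cm^-1.
#: The boundary belongs to both halves (closed intervals); on the default
#: 8 cm^-1 grid it falls between grid points, so no point is shared.
VNIR = SpectralRegion("VNIR", 4_000.0, 12_000.0)
SWNIR = SpectralRegion("SWNIR", 9_091.0, 12_000.0)
LWNIR = SpectralRegion("LWNIR", 4_000.0, 9_091.0)

REGIONS = {r.name: r for r in (VNIR, SWNIR, LWNIR)}
# common aliases
REGIONS["SW-NIR"] = SWNIR
REGIONS["LW-NIR"] = LWNIR


def get_region(name: str | SpectralRegion) -> SpectralRegion:
    """Look up a named region, case-insensitively."""
    if isinstance(name, SpectralRegion):
        return name
    key = name.strip().upper()
    if key not in REGIONS:
        raise EmptyRegionError(
            f"unknown spectral region {name!r}; expected one of {sorted(set(REGIONS))}"
        )
    return REGIONS[key]
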