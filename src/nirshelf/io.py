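"""Reading, writing and reshaping spectra collections.

The canonical on-disk format is a plain CSV with the wavenumber axis in
the first column and one column per measured spectrum.  Column headers
encode the sample identity as ``<fruit>_day<D>_pos<P>`` (position omitted
for replicate-averaged spectra).

In memory a collection is a :class:`SpectraSet`: a shared
:class:`~nirshelf.grid.SpectrumGrid` plus a pandas DataFrame whose rows
are samples (MultiIndex ``fruit, day, pos``) and whose columns are the
grid wavenumbers.  The raw ``values`` array is therefore directly usable
as an sklearn ``X`` matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GridMismatchError
from .grid import SpectralRegion, SpectrumGrid, get_region

_LABEL_RE = re.compile(r"^(?P<fruit>.+?)_day(?P<day>\d+)(?:_pos(?P<pos>\d+))?$")

#: Sentinel position for replicate-averaged spectra.
AVERAGED = 0


@dataclass
class SpectraSet:
    """Spectra sharing one wavenumber grid.

    ``data`` rows are samples indexed by (fruit, day, pos); columns are
    the grid wavenumbers in descending order.
    """

    grid: SpectrumGrid
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.grid):
            raise GridMismatchError(
                f"{self.data.shape[1]} columns vs {len(self.grid)} grid points"
            )
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise FormatError("spectra contain non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """Sample-by-wavenumber absorbance matrix."""
        return self.data.to_numpy()

    def labels(self) -> list[str]:
        return [format_label(f, d, p) for f, d, p in self.data.index]


def format_label(fruit: str, day: int, pos: int = AVERAGED) -> str:
    base = f"{fruit}_day{int(day)}"
    return base if pos == AVERAGED else f"{base}_pos{int(pos)}"


def parse_label(label: str) -> tuple[str, int, int]:
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise FormatError(
            f"column header {label!r} does not match '<fruit>_day<D>[_pos<P>]'"
        )
    pos = m.group("pos")
    return m.group("fruit"), int(m.group("day")), int(pos) if pos else AVERAGED


def make_spectra_set(
    grid: SpectrumGrid,
    values: np.ndarray,
    index: list[tuple[str, int, int]],
) -> SpectraSet:
    """Assemble a SpectraSet from an array and (fruit, day, pos) tuples."""
    idx = pd.MultiIndex.from_tuples(index, names=["fruit", "day", "pos"])
    df = pd.DataFrame(np.asarray(values, dtype=float), index=idx, columns=grid.wavenumbers)
    return SpectraSet(grid, df)


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a spectra CSV (wavenumber column first, one column per spectrum)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if raw.shape[1] < 2:
        raise FormatError(f"{path.name}: needs a wavenumber column and >= 1 spectrum")
    for col in raw.columns:
        series = pd.to_numeric(raw[col], errors="coerce")
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise FormatError(f"{path.name}: non-numeric cell in column {col!r}, row {row}")
        raw[col] = series
    grid = SpectrumGrid(raw.iloc[:, 0].to_numpy())
    index = [parse_label(c) for c in raw.columns[1:]]
    return make_spectra_set(grid, raw.iloc[:, 1:].to_numpy().T, index)


def write_spectra(spectra: SpectraSet, path: str | Path, *, float_format: str = "%.10g") -> None:
    """Write a SpectraSet to CSV; round-trips with :func:`read_spectra`."""
    body = spectra.data.T.to_numpy()
    cols = ["wavenumber"] + [format_label(f, d, p) for f, d, p in spectra.data.index]
    out = pd.DataFrame(
        np.column_stack([spectra.grid.wavenumbers, body]), columns=cols
    )
    out.to_csv(path, index=False, float_format=float_format)


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average the replicate positions of each (fruit, day).

    Returns one spectrum per fruit-day with position set to the
    ``AVERAGED`` sentinel.  Averaging replicate probe positions reduces
    the placement error of a fibre-optic measurement.
    """
    grouped = spectra.data.groupby(level=["fruit", "day"], sort=True).mean()
    idx = pd.MultiIndex.from_tuples(
        [(f, d, AVERAGED) for f, d in grouped.index], names=["fruit", "day", "pos"]
    )
    grouped.index = idx
    return SpectraSet(spectra.grid, grouped)


def restrict_region(spectra: SpectraSet, region: str | SpectralRegion) -> SpectraSet:
    """Restrict spectra to a closed wavenumber interval."""
    region = get_region(region)
    subgrid, idx = spectra.grid.restrict(region.lo, region.hi)
    return SpectraSet(subgrid, spectra.data.iloc[:, idx])
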