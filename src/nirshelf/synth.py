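"""Synthetic longitudinal storage studies with NIR spectra.

No spectra or titration data are deposited with studies of this kind,
so the pipeline is exercised on generated data carrying the statistical
structure the analysis assumes:

* a cohort of fruits split into equal groups, one group destructively
  titrated per day (group k therefore accumulates k daily spectrum
  sets, each measured at several probe positions);
* a vitamin C trajectory per fruit following zero- or first-order
  degradation kinetics from a truncated-normal initial content;
* spectra built from Gaussian absorption bands on a smooth baseline,
  with the band amplitudes at the five long-wavelength effective
  wavenumbers affine in the vitamin C content (so wavelength selection
  has a recoverable ground truth), plus water-dominated bands that do
  not track vitamin C;
* per-spectrum multiplicative/additive scatter and white noise;
* late-storage decay: a few fruits spoil near the end of storage and
  their spectra become disordered (inflated noise).

The dye-titration arithmetic ``VCC = (V - V0) * T * A / W * 100`` is
implemented directly, and generated titration records are obtained by
inverting it from the true content plus measurement noise, so the
assay round-trips exactly in the noise-free limit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidRecordError
from .grid import SpectrumGrid
from .io import make_spectra_set, read_spectra, write_spectra

__all__ = [
    "TitrationRecord",
    "SyntheticStudyConfig",
    "StudyDataset",
    "titration_vcc",
    "titration_record_for_vcc",
    "simulate_true_trajectory",
    "simulate_spectrum",
    "generate_study",
    "write_study",
    "read_study",
]


# ------------------------------------------------------------- titration

@dataclass(frozen=True)
class TitrationRecord:
    """One 2,6-dichloroindophenol titration.

    V/V0 are the dye volumes consumed by the sample and the blank (mL),
    T the dye titer (mg ascorbic acid per mL), A the dilution multiple
    and W the sample weight (g).
    """

    V: float
    V0: float
    T: float
    A: float
    W: float

    def __post_init__(self) -> None:
        if self.W <= 0 or self.T <= 0:
            raise InvalidRecordError("weight W and titer T must be positive")
        if self.A < 1:
            raise InvalidRecordError("dilution multiple A must be >= 1")
        if self.V0 < 0 or self.V < self.V0:
            raise InvalidRecordError("need V >= V0 >= 0")


def titration_vcc(rec: TitrationRecord) -> float:
    """Vitamin C content (mg/100 g): ``(V - V0) * T * A / W * 100``."""
    return (rec.V - rec.V0) * rec.T * rec.A / rec.W * 100.0


def titration_record_for_vcc(
    vcc: float, *, V0: float = 0.1, T: float = 0.2, A: float = 10.0, W: float = 10.0
) -> TitrationRecord:
    """Invert the titration formula: the record a given content produces."""
    if vcc < 0:
        raise InvalidRecordError("vitamin C content cannot be negative")
    V = V0 + vcc * W / (T * A * 100.0)
    return TitrationRecord(V=V, V0=V0, T=T, A=A, W=W)


# ------------------------------------------------------------ trajectories

def simulate_true_trajectory(vcc0: float, days, form: str = "zero", K: float = 20.677):
    """True vitamin C content over storage time.

    ``zero``: ``max(vcc0 - K t, 0)`` (floored — concentrations cannot go
    negative, unlike the fitted linear model which extrapolates through
    zero); ``first``: ``vcc0 * exp(-K t)``.
    """
    if K < 0:
        raise ConfigError("rate constant K must be non-negative")
    if vcc0 <= 0:
        raise ConfigError("initial content vcc0 must be positive")
    t = np.asarray(days, dtype=float)
    if form == "zero":
        out = np.maximum(vcc0 - K * t, 0.0)
    elif form == "first":
        out = vcc0 * np.exp(-K * t)
    else:
        raise ConfigError(f"unknown kinetic form {form!r}; expected 'zero' or 'first'")
    return float(out) if t.ndim == 0 else out


# ---------------------------------------------------------------- spectra

#: Band table: centre (cm^-1) -> (Gaussian sigma, base amplitude,
#: amplitude slope per mg/100 g).  The five vitamin-C-coupled bands sit
#: at the effective wavenumbers of the long-wavelength calibration; the
#: 10,300 and 4,710 cm^-1 bands are water-dominated and fixed.
_BAND_TABLE: dict[float, tuple[float, float, float]] = {
    10_300.0: (200.0, 0.60, 0.0),
    8_330.0: (120.0, 0.25, 1.2e-3),
    6_900.0: (150.0, 0.45, 0.8e-3),
    5_666.0: (100.0, 0.30, -1.0e-3),
    5_150.0: (130.0, 0.50, 0.6e-3),
    4_710.0: (110.0, 0.35, 0.0),
    4_060.0: (90.0, 0.20, 0.9e-3),
}

DEFAULT_BAND_CENTERS = tuple(_BAND_TABLE)
#: Band centres whose amplitude tracks vitamin C (the planted signal).
VCC_COUPLED_CENTERS = tuple(c for c, (_, _, a1) in _BAND_TABLE.items() if a1 != 0.0)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the emulated study: 72 fruits in 18 groups of 4,
    spectra at 3 probe positions per fruit per day, one group titrated
    per day, initial contents ~ truncated Normal(350, 40) mg/100 g and a
    zero-order loss of 20.677 mg/100 g per day at 20 degC.  Five fruits
    decay late in storage (from day 12) and are flagged; their spectra
    get ``decay_noise_factor`` times the noise.  ``n_decayed=None``
    switches to a per-day Bernoulli spoilage process with
    ``decay_prob_per_day``.
    """

    n_fruits: int = 72
    n_groups: int = 18
    group_size: int = 4
    n_positions: int = 3
    vcc0_mean: float = 350.0
    vcc0_sd: float = 40.0
    rate_K: float = 20.677
    kinetic_form: str = "zero"
    band_centers: tuple = DEFAULT_BAND_CENTERS
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.005
    titration_noise_sd: float = 5.0
    decay_start_day: int = 12
    decay_prob_per_day: float = 0.045
    n_decayed: int | None = 5
    decay_noise_factor: float = 8.0
    titer_T: float = 0.2
    dilution_A: float = 10.0
    weight_W: float = 10.0
    weight_mean: float = 27.5
    weight_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups * self.group_size != self.n_fruits:
            raise ConfigError(
                f"n_groups * group_size must equal n_fruits "
                f"({self.n_groups} * {self.group_size} != {self.n_fruits})"
            )
        for name in (
            "vcc0_sd", "scatter_slope_sd", "scatter_offset_sd", "noise_sd",
            "titration_noise_sd", "rate_K",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.decay_prob_per_day <= 1.0:
            raise ConfigError("decay_prob_per_day must be a probability")
        if self.n_positions < 1 or self.n_groups < 1 or self.group_size < 1:
            raise ConfigError("counts must be >= 1")
        if self.kinetic_form not in ("zero", "first"):
            raise ConfigError("kinetic_form must be 'zero' or 'first'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticStudyConfig":
        raw = json.loads(Path(path).read_text())
        raw["band_centers"] = tuple(raw.get("band_centers", DEFAULT_BAND_CENTERS))
        return cls(**raw)


def _band_params(center: float) -> tuple[float, float, float]:
    if center in _BAND_TABLE:
        return _BAND_TABLE[center]
    return 100.0, 0.3, 0.0  # unlisted custom centre: fixed-amplitude band


def _shape(vcc: float, grid: SpectrumGrid, centers) -> np.ndarray:
    """Noise-free spectral shape for a given vitamin C content."""
    wn = grid.wavenumbers
    # gentle baseline rising toward low wavenumber, as water absorption does
    shape = 0.30 + 1.5e-5 * (wn[0] - wn)
    for c in centers:
        sigma, a0, a1 = _band_params(float(c))
        shape = shape + (a0 + a1 * vcc) * np.exp(-0.5 * ((wn - c) / sigma) ** 2)
    return shape


def simulate_spectrum(
    vcc: float,
    grid: SpectrumGrid,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    *,
    noise_factor: float = 1.0,
) -> np.ndarray:
    """One absorbance vector: scatter * shape(vcc) + offset + noise.

    Deterministic given the generator state; two calls with identically
    seeded generators produce identical vectors.
    """
    if vcc < 0:
        raise ConfigError("vcc must be non-negative")
    shape = _shape(vcc, grid, config.band_centers)
    slope = 1.0 + rng.normal(0.0, config.scatter_slope_sd)
    offset = rng.normal(0.0, config.scatter_offset_sd)
    noise = rng.normal(0.0, config.noise_sd * noise_factor, size=len(grid))
    return slope * shape + offset + noise


# ------------------------------------------------------------------ study

@dataclass
class StudyDataset:
    """A complete synthetic storage study.

    ``spectra``: every measured spectrum (fruit, day, position);
    ``manifest``: one row per fruit (group, titration day, weight,
    decay status, true initial content); ``titrations``: one record per
    fruit from its destruction day; ``truth``: the true content of every
    fruit on every measured day.  Storage time t = day - 1 (day 1 is
    the intake measurement).
    """

    grid: SpectrumGrid
    spectra: SpectraSet
    manifest: pd.DataFrame
    titrations: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticStudyConfig


def _draw_vcc0(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Truncated-normal (positive) initial contents by redraw."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ConfigError("could not draw positive initial contents; check vcc0 mean/sd")


def _decay_assignment(
    cfg: SyntheticStudyConfig, titration_day: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Decay day per fruit (0 = never decays).

    Only fruits still in storage on ``decay_start_day`` are at risk.
    The default mode marks exactly ``n_decayed`` fruits (the emulated
    study's spoilage count); the Bernoulli mode spoils each at-risk
    fruit independently each remaining day.
    """
    n = titration_day.size
    decay_day = np.zeros(n, dtype=int)
    at_risk = np.flatnonzero(titration_day >= cfg.decay_start_day)
    if cfg.n_decayed is not None:
        k = min(cfg.n_decayed, at_risk.size)
        chosen = rng.choice(at_risk, size=k, replace=False) if k else np.empty(0, int)
        for i in chosen:
            decay_day[i] = int(rng.integers(cfg.decay_start_day, titration_day[i] + 1))
    else:
        for i in at_risk:
            for day in range(cfg.decay_start_day, int(titration_day[i]) + 1):
                if rng.random() < cfg.decay_prob_per_day:
                    decay_day[i] = day
                    break
    return decay_day


def generate_study(config: SyntheticStudyConfig | None = None) -> StudyDataset:
    """Generate a full storage study from the configuration.

    Fruit f belongs to group ``f // group_size + 1`` and is titrated on
    the day equal to its group number, so group k carries k daily
    spectrum sets of ``n_positions`` replicate spectra each.
    """
    cfg = config or SyntheticStudyConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = SpectrumGrid.default()

    n = cfg.n_fruits
    fruit_ids = [f"F{i + 1:02d}" for i in range(n)]
    groups = np.repeat(np.arange(1, cfg.n_groups + 1), cfg.group_size)
    titration_day = groups.copy()
    vcc0 = _draw_vcc0(rng, n, cfg.vcc0_mean, cfg.vcc0_sd)
    weights = rng.normal(cfg.weight_mean, cfg.weight_sd, size=n).clip(min=1.0)
    decay_day = _decay_assignment(cfg, titration_day, rng)

    spectra_rows, spectra_index = [], []
    truth_rows = []
    titration_rows = []
    for i, fruit in enumerate(fruit_ids):
        days = np.arange(1, titration_day[i] + 1)
        traj = simulate_true_trajectory(vcc0[i], days - 1, cfg.kinetic_form, cfg.rate_K)
        traj = np.atleast_1d(traj)
        for day, vcc_true in zip(days, traj):
            decayed_now = decay_day[i] > 0 and day >= decay_day[i]
            factor = cfg.decay_noise_factor if decayed_now else 1.0
            for pos in range(1, cfg.n_positions + 1):
                spectra_rows.append(
                    simulate_spectrum(vcc_true, grid, cfg, rng, noise_factor=factor)
                )
                spectra_index.append((fruit, int(day), pos))
            truth_rows.append(
                {"fruit": fruit, "day": int(day), "t": float(day - 1),
                 "vcc_true": float(vcc_true), "vcc0_true": float(vcc0[i])}
            )
        # destructive titration on the final day, from the true content
        observed = traj[-1] + rng.normal(0.0, cfg.titration_noise_sd)
        observed = max(observed, 0.0)
        rec = titration_record_for_vcc(
            observed, T=cfg.titer_T, A=cfg.dilution_A, W=cfg.weight_W
        )
        titration_rows.append(
            {"fruit": fruit, "day": int(titration_day[i]),
             "V": rec.V, "V0": rec.V0, "T": rec.T, "A": rec.A, "W": rec.W,
             "vcc": titration_vcc(rec)}
        )

    spectra = make_spectra_set(grid, np.vstack(spectra_rows), spectra_index)
    manifest = pd.DataFrame(
        {
            "fruit": fruit_ids,
            "group": groups,
            "titration_day": titration_day,
            "weight_g": weights,
            "decayed": decay_day > 0,
            "decay_day": decay_day,
            "vcc0_true": vcc0,
        }
    )
    return StudyDataset(
        grid=grid,
        spectra=spectra,
        manifest=manifest,
        titrations=pd.DataFrame(titration_rows),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


# --------------------------------------------------------------- study IO

def write_study(dataset: StudyDataset, directory: str | Path) -> dict[str, Path]:
    """Write a study as one directory of CSVs plus a config JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": directory / "spectra.csv",
        "manifest": directory / "manifest.csv",
        "titrations": directory / "titrations.csv",
        "truth": directory / "truth.csv",
        "config": directory / "config.json",
    }
    write_spectra(dataset.spectra, paths["spectra"])
    dataset.manifest.to_csv(paths["manifest"], index=False)
    dataset.titrations.to_csv(paths["titrations"], index=False)
    dataset.truth.to_csv(paths["truth"], index=False)
    dataset.config.to_json(paths["config"])
    return paths


def read_study(directory: str | Path) -> StudyDataset:
    """Read a study directory written by :func:`write_study`."""
    directory = Path(directory)
    spectra = read_spectra(directory / "spectra.csv")
    manifest = pd.read_csv(directory / "manifest.csv")
    titrations = pd.read_csv(directory / "titrations.csv")
    truth = pd.read_csv(directory / "truth.csv")
    config = SyntheticStudyConfig.from_json(directory / "config.json")
    return StudyDataset(
        grid=spectra.grid,
        spectra=spectra,
        manifest=manifest,
        titrations=titrations,
        truth=truth,
        config=config,
    )
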