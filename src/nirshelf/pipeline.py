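"""End-to-end orchestration of the storage-study analysis.

``run_pipeline`` sequences the full chain on one study directory:

    (simulate) -> read -> average replicates -> pretreat -> restrict
    region -> split -> select wavenumbers -> fit MLR -> evaluate ->
    fit kinetics -> compare -> shelf-life report

writing model JSONs, metrics CSVs and a run log.  Re-running with the
same configuration reproduces every artifact, since all randomness is
funnelled through the recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .calibrate import (
    DEFAULT_N_SELECT,
    MLRCalibration,
    SplitSpec,
    assemble_calibration,
    compare_pretreatments,
    evaluate,
    predict_vcc,
    split_samples,
)
from .errors import ConfigError
from .grid import get_region
from .io import average_replicates
from .kinetics import compare_kinetics, fit_first_order, fit_zero_order
from .pretreat import PRETREATMENT_ORDER, canonical_method, make_pretreatment
from .shelflife import safe_storage_time
from .synth import StudyDataset, SyntheticStudyConfig, generate_study, read_study, write_study


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    study_dir: str | None = None  # None -> simulate into output_dir/study
    output_dir: str = "nirshelf_run"
    pretreatment: str = "msc"
    region: str = "LWNIR"
    n_select: int | None = None  # None -> conventional default per method
    split: SplitSpec = field(default_factory=SplitSpec)
    simulate: SyntheticStudyConfig | None = None
    shelf_life_method: str = "algebraic"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "split" in raw:
            raw["split"] = SplitSpec(**raw["split"])
        if raw.get("simulate") is not None:
            raw["simulate"] = SyntheticStudyConfig(**raw["simulate"])
        return cls(**raw)

    def validate(self) -> None:
        canonical_method(self.pretreatment)
        get_region(self.region)
        if self.study_dir is None and self.simulate is None:
            self.simulate = SyntheticStudyConfig(seed=self.seed)
        if self.study_dir is not None and not Path(self.study_dir).is_dir():
            raise ConfigError(f"study directory {self.study_dir!r} does not exist")

    def digest(self) -> str:
        payload = {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _fit_study_kinetics(dataset: StudyDataset, mlr: MLRCalibration, transformer, region_idx):
    """Kinetic fit on titrated contents vs storage time.

    The initial content VCC0 of every fruit is predicted by the MLR
    calibration from its day-1 (intake) spectrum; the response is the
    titrated content on the destruction day, at storage time
    t = day - 1.
    """
    averaged = average_replicates(dataset.spectra)
    tit = dataset.titrations
    vcc, vcc0, t = [], [], []
    for _, rec in tit.iterrows():
        fruit, day = rec["fruit"], int(rec["day"])
        day1 = averaged.data.loc[(fruit, 1, 0)].to_numpy()[None, :]
        day1 = transformer.transform(day1)[:, region_idx]
        vcc0.append(float(predict_vcc(mlr, mlr_selected(mlr, day1))[0]))
        vcc.append(float(rec["vcc"]))
        t.append(float(day - 1))
    vcc, vcc0, t = map(np.asarray, (vcc, vcc0, t))
    zero = fit_zero_order(vcc, vcc0, t)
    first = fit_first_order(vcc, t)
    comparison = compare_kinetics(zero, first, vcc, vcc0, t)
    return zero, first, comparison, vcc0


def mlr_selected(mlr: MLRCalibration, X_region: np.ndarray) -> np.ndarray:
    """Slice the model's selected columns out of a region-restricted X."""
    return X_region[:, mlr.selected_idx_]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the artifact manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- study: simulate or load -----------------------------------
    if config.study_dir is None:
        dataset = generate_study(config.simulate)
        study_dir = out / "study"
        write_study(dataset, study_dir)
        artifacts["study"] = str(study_dir)
    else:
        dataset = read_study(config.study_dir)
        artifacts["study"] = str(config.study_dir)

    region = get_region(config.region)
    method = canonical_method(config.pretreatment)
    n_select = config.n_select
    if n_select is None:
        n_select = 5 if region.name == "LWNIR" else DEFAULT_N_SELECT[method]

    # --- pretreatment comparison table (shared split) ---------------
    # conventional characteristic-wavenumber counts, capped so that the
    # OLS stays overdetermined on small calibration sets
    cap = max(config.split.n_calibration - 2, 1)
    table = compare_pretreatments(
        dataset, PRETREATMENT_ORDER, region=region,
        n_select={m: min(DEFAULT_N_SELECT[m], cap) for m in PRETREATMENT_ORDER},
        split=config.split,
    )
    table_path = out / "pretreatment_metrics.csv"
    table.to_csv(table_path, float_format="%.6g")
    artifacts["pretreatment_metrics"] = str(table_path)

    # --- calibration with the configured pretreatment ---------------
    spectra, y = assemble_calibration(dataset)
    cal_ids, pred_ids = split_samples(dataset, config.split)
    transformer = make_pretreatment(method, spacing=spectra.grid.spacing)
    in_cal = spectra.data.index.get_level_values("fruit").isin(cal_ids)
    in_pred = spectra.data.index.get_level_values("fruit").isin(pred_ids)
    X_cal = spectra.data.loc[in_cal].to_numpy()
    X_pred = spectra.data.loc[in_pred].to_numpy()
    transformer.fit(X_cal)
    _, ridx = spectra.grid.restrict(region.lo, region.hi)
    wn = spectra.grid.wavenumbers[ridx]
    Xc = transformer.transform(X_cal)[:, ridx]
    Xp = transformer.transform(X_pred)[:, ridx]
    y_cal = y.loc[spectra.data.index.get_level_values("fruit")[in_cal]].to_numpy()
    y_pred = y.loc[spectra.data.index.get_level_values("fruit")[in_pred]].to_numpy()

    mlr = MLRCalibration(n_select=n_select, wavenumbers=wn).fit(Xc, y_cal)
    metrics = evaluate(mlr, Xc, y_cal, Xp, y_pred, method=method)
    mlr_path = out / "mlr_model.json"
    mlr_path.write_text(json.dumps(
        {**mlr.to_dict(), "pretreatment": method, "region": region.name,
         "split_seed": config.split.seed, "metrics": metrics.as_row()}, indent=2))
    artifacts["mlr_model"] = str(mlr_path)

    # --- kinetics ----------------------------------------------------
    zero, first, comparison, vcc0_pred = _fit_study_kinetics(dataset, mlr, transformer, ridx)
    for name, model in (("zero_order", zero), ("first_order", first)):
        p = out / f"{name}_model.json"
        p.write_text(json.dumps({**model.to_dict(), "seed": config.seed}, indent=2))
        artifacts[name] = str(p)
    comp_path = out / "kinetics_comparison.csv"
    comp_table = comparison.as_table()
    comp_table.loc["chosen"] = ["yes" if comparison.chosen == "zero" else "no",
                                "yes" if comparison.chosen == "first" else "no"]
    comp_table.to_csv(comp_path, float_format="%.6g")
    artifacts["kinetics_comparison"] = str(comp_path)

    # --- shelf life --------------------------------------------------
    shelf = {}
    if zero.rate_ > 0:
        times = [safe_storage_time(zero, float(v)) for v in vcc0_pred]
        shelf = {
            "threshold_mg_per_100g": 0.0,
            "mean_safe_storage_days": float(np.mean(times)),
            "min_safe_storage_days": float(np.min(times)),
            "max_safe_storage_days": float(np.max(times)),
        }
    shelf_path = out / "shelf_life.json"
    shelf_path.write_text(json.dumps(shelf, indent=2))
    artifacts["shelf_life"] = str(shelf_path)

    # --- run log -----------------------------------------------------
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(
        {"config_digest": config.digest(), "seed": config.seed,
         "split_seed": config.split.seed, "artifacts": artifacts}, indent=2))
    artifacts["run_log"] = str(log_path)
    return artifacts
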