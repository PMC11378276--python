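"""End-to-end orchestration: split, calibrate, validate, predict unknowns.

``calibrate`` runs align -> normalize -> stratified split -> calibration-
fitted scaling -> OPS-PLS and reports the six standard figures of merit
(RMSEC/Rc, RMSECV/Rcv, RMSEP/Rp). ``predict_unknowns`` applies a fitted
model to new spectra and corrects each prediction by its dilution factor.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ManifestError, UndefinedCorrelationError
from .ops_selection import OPSResult, ops_select, ops_select_scan
from .pls_core import PLSModel, correlation, predict, rmse
from .preprocess import normalize_rows
from .spectra_io import (
    AlignedMatrix,
    BinGrid,
    Spectrum,
    align_spectra,
    bin_spectrum,
    load_manifest_spectra,
    read_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the quantification pipeline (YAML-mappable)."""

    mz_min: float = 100.0
    mz_max: float = 400.0
    resolution: float = 0.001
    normalization: str = "sum"
    scaling: str = "autoscale"
    max_lv: int = 10
    leave_out: int = 3
    n_splits: int = 200
    n_cal: int = 24
    n_pred: int = 12
    seed: int = 0
    ops_window: int = 20
    ops_increment: int = 5
    ops_percent: float = 100.0
    ops_kind: str = "regression"  # one informative kind, or "scan" for all
    ops_iterations: int = 1
    dilution_factor: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def split_samples(
    y: np.ndarray, n_cal: int = 24, n_pred: int = 12, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/prediction split stratified on concentration level.

    Samples are grouped by level; per-level calibration quotas follow a
    largest-remainder apportionment, then the global minimum and maximum
    levels are forced to contribute at least one calibration sample (and one
    prediction sample when replicates allow) so both sets span the modeled
    range. Falls back to a plain random split, with a warning, when there
    are too few levels to honor the range constraint.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n_cal + n_pred != n:
        raise ValueError("n_cal + n_pred must equal the number of samples")
    if n_cal < 1 or n_pred < 0:
        raise ValueError("need at least one calibration sample")
    rng = np.random.default_rng(seed)
    levels = np.unique(y)
    if levels.size < 2:
        logger.warning("fewer than 2 levels; plain random split")
        perm = rng.permutation(n)
        return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
    members = {lv: np.flatnonzero(y == lv) for lv in levels}
    counts = {lv: members[lv].size for lv in levels}
    # largest-remainder apportionment of the calibration quota
    ideal = {lv: n_cal * counts[lv] / n for lv in levels}
    quota = {lv: int(np.floor(ideal[lv])) for lv in levels}
    remainder = n_cal - sum(quota.values())
    order = sorted(levels, key=lambda lv: (-(ideal[lv] - quota[lv]), rng.random()))
    for lv in order[:remainder]:
        quota[lv] += 1
    # range constraint: extreme levels contribute >=1 calibration sample,
    # and >=1 prediction sample when they have spare replicates
    for lv in (levels[0], levels[-1]):
        if quota[lv] == 0:
            donor = max(levels, key=lambda l: quota[l] - (l in (levels[0], levels[-1])))
            if quota[donor] == 0:
                logger.warning("cannot honor range constraint; plain random split")
                perm = rng.permutation(n)
                return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
            quota[donor] -= 1
            quota[lv] += 1
        if n_pred > 0 and counts[lv] > 1 and quota[lv] == counts[lv]:
            recipient = min(
                (l for l in levels if quota[l] < counts[l]),
                key=lambda l: quota[l] / counts[l],
                default=None,
            )
            if recipient is not None:
                quota[lv] -= 1
                quota[recipient] += 1
    cal: list[int] = []
    for lv in levels:
        picked = rng.choice(members[lv], size=quota[lv], replace=False)
        cal.extend(int(i) for i in picked)
    cal_idx = np.sort(np.asarray(cal, dtype=np.int64))
    pred_idx = np.setdiff1d(np.arange(n), cal_idx)
    return cal_idx, pred_idx


@dataclass
class CalibrationReport:
    """The six standard figures of merit plus model bookkeeping."""

    pretreatment: str
    n_lv: int
    rmsec: float
    rc: float
    rmsecv: float
    rcv: float
    rmsep: float
    rp: float
    n_variables_selected: int
    split_seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        lines = [
            f"pretreatment          {self.pretreatment}",
            f"LV                    {self.n_lv}",
            f"RMSEC                 {self.rmsec:.4f}",
            f"Rc                    {self.rc:.4f}",
            f"RMSECV                {self.rmsecv:.4f}",
            f"Rcv                   {self.rcv:.4f}",
            f"RMSEP                 {self.rmsep:.4f}",
            f"Rp                    {self.rp:.4f}",
            f"variables selected    {self.n_variables_selected}",
            f"split seed            {self.split_seed}",
        ]
        return "\n".join(lines)


@dataclass
class ModelBundle:
    """A fitted calibration model plus everything needed to apply it."""

    grid: BinGrid
    model: PLSModel  # carries scaler + selected column indices
    config: PipelineConfig
    ops: OPSResult | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "grid": {
                "mz_min": self.grid.mz_min,
                "mz_max": self.grid.mz_max,
                "resolution": self.grid.resolution,
                "occupied_bins": self.grid.occupied_bins.tolist(),
            },
            "config": dataclasses.asdict(self.config),
        }
        path.write_text(json.dumps(payload))
        self.model.to_json(path.with_suffix(".model.json"))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        d = json.loads(path.read_text())
        g = d["grid"]
        grid = BinGrid(
            g["mz_min"], g["mz_max"], g["resolution"], np.asarray(g["occupied_bins"])
        )
        model = PLSModel.from_json(path.with_suffix(".model.json"))
        return cls(grid=grid, model=model, config=PipelineConfig(**d["config"]))

    def matrix_for(self, spectra: list[Spectrum]) -> np.ndarray:
        """Raw intensity matrix of new spectra over the training bin grid.

        Peaks in bins the calibration never occupied are dropped (they have
        no model column).
        """
        col = {int(b): j for j, b in enumerate(self.grid.occupied_bins)}
        X = np.zeros((len(spectra), len(col)))
        for i, s in enumerate(spectra):
            sparse = bin_spectrum(
                s, self.grid.mz_min, self.grid.mz_max, self.grid.resolution
            )
            for b, inten in sparse.items():
                j = col.get(b)
                if j is not None:
                    X[i, j] = inten
        return X


def calibrate(
    spectra: list[Spectrum], y: np.ndarray, config: PipelineConfig | None = None
) -> tuple[CalibrationReport, ModelBundle]:
    """Full calibration run on in-memory spectra with known concentrations."""
    config = config or PipelineConfig()
    y = np.asarray(y, dtype=np.float64)
    t0 = time.perf_counter()
    matrix, grid = align_spectra(spectra, config.mz_min, config.mz_max, config.resolution)
    logger.info(
        "stage=align n_samples=%d n_bins=%d elapsed=%.2fs",
        matrix.n_samples, matrix.n_bins, time.perf_counter() - t0,
    )
    Xn = normalize_rows(matrix.X, config.normalization, sample_ids=matrix.sample_ids)
    cal_idx, pred_idx = split_samples(y, config.n_cal, config.n_pred, config.seed)
    return _calibrate_split(Xn, y, cal_idx, pred_idx, grid, config)


def _calibrate_split(Xn, y, cal_idx, pred_idx, grid, config):
    t0 = time.perf_counter()
    lv_grid = range(1, config.max_lv + 1)
    kwargs = dict(
        window=config.ops_window,
        increment=config.ops_increment,
        percent=config.ops_percent,
        scaling=config.scaling,
        leave_out=config.leave_out,
        n_splits=config.n_splits,
        seed=config.seed,
        iterations=config.ops_iterations,
    )
    if config.ops_kind == "scan":
        ops = ops_select_scan(Xn[cal_idx], y[cal_idx], lv_grid, **kwargs)
    else:
        ops = ops_select(Xn[cal_idx], y[cal_idx], lv_grid, kind=config.ops_kind, **kwargs)
    logger.info(
        "stage=ops n_selected=%d n_lv=%d elapsed=%.2fs",
        ops.selected_columns.size, ops.selected_model.n_lv, time.perf_counter() - t0,
    )
    model = ops.selected_model
    cal_metrics = ops.selected_metrics["calibration"]
    cv_metrics = ops.selected_metrics["cross-validation"]
    if pred_idx.size:
        y_pred = predict(model, Xn[pred_idx])
        rmsep = rmse(y[pred_idx], y_pred)
        try:
            rp = correlation(y[pred_idx], y_pred)
        except UndefinedCorrelationError:
            rp = float("nan")
    else:
        rmsep, rp = float("nan"), float("nan")
    report = CalibrationReport(
        pretreatment=f"{config.scaling} normalization by {config.normalization}",
        n_lv=model.n_lv,
        rmsec=cal_metrics.rmse,
        rc=cal_metrics.r,
        rmsecv=cv_metrics.rmse,
        rcv=cv_metrics.r,
        rmsep=rmsep,
        rp=rp,
        n_variables_selected=int(ops.selected_columns.size),
        split_seed=config.seed,
    )
    bundle = ModelBundle(grid=grid, model=model, config=config, ops=ops)
    return report, bundle


def run_calibration(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    base_dir: str | Path | None = None,
) -> tuple[CalibrationReport, ModelBundle]:
    """Calibrate from a manifest CSV referencing spectrum files.

    Rows with roles calibration/prediction define the split when both are
    present; otherwise a stratified random split of all rows with known
    concentrations is used.
    """
    config = config or PipelineConfig()
    manifest = read_manifest(manifest_path)
    base = base_dir if base_dir is not None else Path(manifest_path).parent
    known = manifest[manifest["role"].isin(["calibration", "prediction"])]
    if known["concentration_mg_per_L"].isna().any():
        missing = known.loc[
            known["concentration_mg_per_L"].isna(), "sample_id"
        ].tolist()
        raise ManifestError(f"missing concentrations for samples {missing}")
    if known["concentration_mg_per_L"].nunique() < 2:
        raise ManifestError("need at least 2 distinct calibration levels")
    spectra = load_manifest_spectra(known, base)
    y = known["concentration_mg_per_L"].to_numpy(dtype=np.float64)
    roles = known["role"].to_numpy()
    if (roles == "calibration").any() and (roles == "prediction").any():
        matrix, grid = align_spectra(
            spectra, config.mz_min, config.mz_max, config.resolution
        )
        Xn = normalize_rows(matrix.X, config.normalization, sample_ids=matrix.sample_ids)
        cal_idx = np.flatnonzero(roles == "calibration")
        pred_idx = np.flatnonzero(roles == "prediction")
        return _calibrate_split(Xn, y, cal_idx, pred_idx, grid, config)
    return calibrate(spectra, y, config)


@dataclass
class PredictionRecord:
    """One unknown sample's prediction with dilution correction."""

    sample_id: str
    predicted_instrument_level: float  # mg/L in the (diluted) analyzed extract
    dilution_factor: float
    corrected_concentration: float = field(init=False)
    reference_value: float | None = None
    difference: float | None = field(init=False, default=None)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        self.corrected_concentration = (
            self.predicted_instrument_level * self.dilution_factor
        )
        if self.reference_value is not None:
            self.difference = self.corrected_concentration - self.reference_value
        if self.predicted_instrument_level < 0 and "below calibration range" not in self.flags:
            self.flags.append("below calibration range")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "predicted_instrument_level": self.predicted_instrument_level,
            "dilution_factor": self.dilution_factor,
            "corrected_concentration": self.corrected_concentration,
            "reference_value": self.reference_value,
            "difference": self.difference,
            "flags": list(self.flags),
        }


@dataclass
class PredictionSummary:
    mean_difference: float | None
    r_vs_reference: float | None
    n: int


def predict_unknowns(
    bundle: ModelBundle,
    spectra: list[Spectrum],
    dilution_factor: float | None = None,
    references: dict[str, float] | None = None,
) -> tuple[list[PredictionRecord], PredictionSummary]:
    """Predict unknown spectra and correct by the dilution factor.

    ``dilution_factor`` overrides per-spectrum factors when given. With
    references supplied, the summary carries the mean (corrected - reference)
    difference and the Pearson correlation of corrected vs reference.
    """
    X = bundle.matrix_for(spectra)
    Xn = normalize_rows(
        X, bundle.config.normalization, sample_ids=[s.sample_id for s in spectra]
    )
    y_hat = predict(bundle.model, Xn)
    records = []
    for s, p1 in zip(spectra, np.atleast_1d(y_hat)):
        df = dilution_factor if dilution_factor is not None else s.dilution_factor
        ref = references.get(s.sample_id) if references else None
        records.append(
            PredictionRecord(
                sample_id=s.sample_id,
                predicted_instrument_level=float(p1),
                dilution_factor=float(df),
                reference_value=ref,
            )
        )
    return records, summarize_predictions(records)


def summarize_predictions(records: list[PredictionRecord]) -> PredictionSummary:
    """Mean difference and Pearson r vs reference over records that have one."""
    with_ref = [r for r in records if r.reference_value is not None]
    if not with_ref:
        return PredictionSummary(None, None, len(records))
    diffs = np.asarray([r.difference for r in with_ref])
    mean_diff = float(diffs.mean())
    r = None
    if len(with_ref) >= 2:
        try:
            r = correlation(
                np.asarray([r.corrected_concentration for r in with_ref]),
                np.asarray([r.reference_value for r in with_ref]),
            )
        except UndefinedCorrelationError:
            r = None
    return PredictionSummary(mean_diff, r, len(records))
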