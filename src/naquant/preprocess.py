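"""Row normalization and calibration-fitted column scaling.

Pipeline order is: normalize rows (per-sample, so split-order immaterial),
then fit the column scaler on calibration rows only and apply its statistics
to any later data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateRowError, NotFittedError
from .spectra_io import AlignedMatrix

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("none", "sum", "max", "vector")
SCALINGS = ("center", "autoscale")


def normalize_rows(X, method: str = "sum", sample_ids=None):
    """Row-wise normalization: 'sum' (total=1), 'max', 'vector' or 'none'.

    Accepts a bare array or an AlignedMatrix (returned as the same type).
    An all-zero row raises, naming the offending sample.
    """
    if isinstance(X, AlignedMatrix):
        Xn = normalize_rows(X.X, method, sample_ids=X.sample_ids)
        return AlignedMatrix(Xn, X.bin_centers, list(X.sample_ids))
    X = np.asarray(X, dtype=np.float64)
    if method == "none":
        return X.copy()
    if method == "sum":
        denom = X.sum(axis=1)
    elif method == "max":
        denom = X.max(axis=1, initial=0.0)
    elif method == "vector":
        denom = np.linalg.norm(X, axis=1)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        raise DegenerateRowError(f"cannot normalize all-zero row for sample {name}")
    return X / denom[:, None]


@dataclass
class Scaler:
    """Column scaler with calibration statistics (mean/SD, sample SD n-1)."""

    method: str = "autoscale"
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    retained_columns: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0
    _fitted: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.method not in SCALINGS:
            raise ValueError(f"scaling method must be one of {SCALINGS}")

    def _check(self) -> None:
        if not self._fitted:
            raise NotFittedError("scaler has not been fitted")

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Scale new data with the stored calibration statistics."""
        self._check()
        X = np.asarray(X, dtype=np.float64)[:, self.retained_columns]
        X = X - self.column_means
        if self.method == "autoscale":
            X = X / self.column_sds
        return X

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        self._check()
        y = np.asarray(y, dtype=np.float64)
        return (y - self.y_mean) / self.y_sd

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(y_scaled, dtype=np.float64) * self.y_sd + self.y_mean


def fit_scaler(X_cal: np.ndarray, y_cal: np.ndarray, method: str = "autoscale") -> Scaler:
    """Fit column means (and SDs for autoscale) on calibration data only.

    Zero-variance calibration columns are dropped and logged; y is centered
    for both methods and additionally SD-scaled under autoscale.
    """
    X_cal = np.asarray(X_cal, dtype=np.float64)
    y_cal = np.asarray(y_cal, dtype=np.float64)
    if X_cal.ndim != 2 or X_cal.shape[0] != y_cal.shape[0]:
        raise ValueError("X_cal and y_cal must have matching sample counts")
    means = X_cal.mean(axis=0)
    sds = X_cal.std(axis=0, ddof=1) if X_cal.shape[0] > 1 else np.zeros(X_cal.shape[1])
    retained = np.flatnonzero(sds > 0)
    if retained.size < X_cal.shape[1]:
        logger.info(
            "dropped %d zero-variance columns of %d",
            X_cal.shape[1] - retained.size, X_cal.shape[1],
        )
    y_sd = float(np.std(y_cal, ddof=1)) if y_cal.size > 1 else 0.0
    scaler = Scaler(
        method=method,
        column_means=means[retained],
        column_sds=sds[retained] if method == "autoscale" else None,
        retained_columns=retained,
        y_mean=float(y_cal.mean()),
        y_sd=y_sd if (method == "autoscale" and y_sd > 0) else 1.0,
    )
    scaler._fitted = True
    return scaler
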