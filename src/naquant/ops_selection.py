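"""Ordered predictor selection (OPS).

Variables are ranked by an informative vector derived from a pilot PLS
model, then nested prefixes of the ranking (window, window + increment, ...)
are each scored by cross-validated RMSE; the best prefix and its LV count
win. The identical split set is reused for every prefix so RMSECV values
are directly comparable — in particular the full variable set is always a
candidate at percent=100, so the winner can never be worse than no
selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedCorrelationError
from .pls_core import (
    CVResult,
    Metrics,
    PLSModel,
    correlation,
    cross_validate,
    fit_pls,
    make_splits,
    predict,
    rmse,
)
from .preprocess import fit_scaler

logger = logging.getLogger(__name__)

INFORMATIVE_KINDS = ("regression", "correlation", "product")


def informative_vector(
    X: np.ndarray, y: np.ndarray, model: PLSModel, kind: str = "regression"
) -> np.ndarray:
    """Per-variable importance in [0, 1], unit maximum.

    ``regression``: |b| of the pilot model; ``correlation``: |Pearson r|
    of each column with y (zero-variance columns scored 0); ``product``:
    elementwise product of the two rescaled factors (not rescaled again, so
    it stays below each factor).
    """
    if kind not in INFORMATIVE_KINDS:
        raise ValueError(f"kind must be one of {INFORMATIVE_KINDS}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()

    def _rescale(v: np.ndarray) -> np.ndarray:
        m = v.max()
        return v / m if m > 0 else v

    if kind in ("regression", "product"):
        reg = _rescale(np.abs(model.regression_vector))
        if kind == "regression":
            return reg
    corr = np.zeros(X.shape[1])
    dy = y - y.mean()
    sy = np.sqrt((dy**2).sum())
    dX = X - X.mean(axis=0)
    sx = np.sqrt((dX**2).sum(axis=0))
    ok = (sx > 0) & (sy > 0)
    if not ok.all():
        logger.info("%d zero-variance columns scored 0 in |corr|", (~ok).sum())
    corr[ok] = np.abs(dX[:, ok].T @ dy) / (sx[ok] * sy)
    corr = _rescale(corr)
    if kind == "correlation":
        return corr
    return reg * corr


def window_sizes(p: int, window: int, increment: int, percent: float) -> list[int]:
    """Arithmetic progression of prefix sizes: window, window+inc, ... <= L
    with L = ceil(percent/100 * p); L itself is appended when missed, and p
    is appended at percent=100 if not already present."""
    if window < 1 or increment < 1:
        raise ValueError("window and increment must be >= 1")
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    if window >= p:
        return [p]
    limit = math.ceil(percent / 100.0 * p)
    sizes = list(range(window, limit + 1, increment))
    if not sizes or sizes[-1] != limit:
        sizes.append(limit)
    if percent == 100 and sizes[-1] != p:
        sizes.append(p)
    return sizes


@dataclass
class OPSResult:
    """Outcome of one OPS pass."""

    informative_kind: str
    ordering: np.ndarray  # permutation of column indices, most informative first
    window_trace: list[tuple[int, int, float]]  # (subset_size, best_lv, rmsecv)
    selected_columns: np.ndarray  # prefix of ordering, sorted for modelling
    selected_model: PLSModel
    selected_cv: CVResult
    selected_metrics: dict[str, Metrics]

    @property
    def selected_rmsecv(self) -> float:
        return min(t[2] for t in self.window_trace)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.window_trace, columns=["subset_size", "best_lv", "rmsecv"]
        )


def ops_select(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid,
    window: int = 20,
    increment: int = 5,
    percent: float = 100.0,
    kind: str = "regression",
    scaling: str = "autoscale",
    leave_out: int = 3,
    n_splits: int = 200,
    seed: int | None = 0,
    iterations: int = 1,
) -> OPSResult:
    """OPS on a (row-normalized) calibration matrix.

    1. pilot PLS on all variables, LV by CV; 2. informative vector and
    descending sort; 3. CV of every prefix in the window progression;
    4. winner = minimal RMSECV, ties toward fewer variables then fewer LVs;
    5. refit on the full calibration set restricted to the winning prefix.

    ``iterations > 1`` repeats the rank-and-evaluate pass on the previously
    selected subset (iterated OPS), stopping early when the selection is
    stable. Column indices in the result always refer to the input X.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    cols = np.arange(X.shape[1])
    result = None
    for _ in range(iterations):
        result = _ops_pass(
            X[:, cols], y, lv_grid, window, increment, percent, kind,
            scaling, leave_out, n_splits, seed,
        )
        # lift pass-local indices back to the input matrix
        result.ordering = cols[result.ordering]
        result.selected_columns = cols[result.selected_columns]
        result.selected_model.columns = result.selected_columns
        if result.selected_columns.size == cols.size:
            break
        cols = result.selected_columns
    return result


def ops_select_scan(X, y, lv_grid, kinds=INFORMATIVE_KINDS, **kwargs) -> OPSResult:
    """Run OPS once per informative-vector kind and keep the RMSECV-best."""
    results = {k: ops_select(X, y, lv_grid, kind=k, **kwargs) for k in kinds}
    for k, r in results.items():
        logger.info("OPS scan: kind=%s rmsecv=%.4g", k, r.selected_cv.rmsecv)
    best = min(results.values(), key=lambda r: r.selected_cv.rmsecv)
    logger.info("OPS scan winner: %s", best.informative_kind)
    return best


def _ops_pass(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid,
    window: int,
    increment: int,
    percent: float,
    kind: str,
    scaling: str,
    leave_out: int,
    n_splits: int,
    seed: int | None,
) -> OPSResult:
    n, p = X.shape
    splits = make_splits(n, leave_out, n_splits, seed)
    lv_grid = sorted(set(int(a) for a in lv_grid))

    pilot_cv = cross_validate(X, y, lv_grid, scaling=scaling, splits=splits, seed=seed)
    scaler = fit_scaler(X, y, method=scaling)
    Xs, ys = scaler.apply(X), scaler.transform_y(y)
    pilot = fit_pls(Xs, ys, min(pilot_cv.chosen_lv, min(Xs.shape[0] - 1, Xs.shape[1])))

    info_retained = informative_vector(Xs, ys, pilot, kind)
    info = np.zeros(p)
    info[scaler.retained_columns] = info_retained
    # stable sort on (-info, index): descending informativeness, index tie-break
    ordering = np.lexsort((np.arange(p), -info))

    trace: list[tuple[int, int, float]] = []
    cv_by_size: dict[int, CVResult] = {}
    for size in window_sizes(p, window, increment, percent):
        cols = ordering[:size]
        cv = cross_validate(
            X[:, cols], y, lv_grid, scaling=scaling, splits=splits, seed=seed
        )
        trace.append((size, cv.chosen_lv, cv.rmsecv))
        cv_by_size[size] = cv

    best_size, best_lv, _ = min(trace, key=lambda t: (t[2], t[0], t[1]))
    best_cv = cv_by_size[best_size]
    selected = ordering[:best_size]  # kept in ranking order (prefix of ordering)

    final_scaler = fit_scaler(X[:, selected], y, method=scaling)
    Xf = final_scaler.apply(X[:, selected])
    yf = final_scaler.transform_y(y)
    model = fit_pls(Xf, yf, min(best_lv, min(Xf.shape[0] - 1, Xf.shape[1])))
    model.scaler = final_scaler
    model.columns = selected

    y_fit = predict(model, X)
    try:
        rc = correlation(y, y_fit)
    except UndefinedCorrelationError:
        rc = float("nan")
    metrics = {
        "calibration": Metrics(rmse(y, y_fit), rc, n, "calibration"),
        "cross-validation": Metrics(
            best_cv.rmsecv, best_cv.rcv, n, "cross-validation"
        ),
    }
    logger.info(
        "OPS(%s): selected %d of %d variables, %d LV, RMSECV %.4g",
        kind, best_size, p, model.n_lv, best_cv.rmsecv,
    )
    return OPSResult(
        informative_kind=kind,
        ordering=ordering,
        window_trace=trace,
        selected_columns=selected,
        selected_model=model,
        selected_cv=best_cv,
        selected_metrics=metrics,
    )
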