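"""PLS1 regression (NIPALS), error/correlation metrics and Monte-Carlo CV.

For a single response the NIPALS weight computation is closed-form per
component: w = X'y/||X'y||, t = Xw, p = X't/t't, q = y't/t't, then X and y
are deflated. The regression vector for a LVs is b = W (P'W)^{-1} q.
Cross-validation repeatedly removes a small random group of samples
(default three), refits preprocessing and PLS on the remainder, and pools
held-out residuals per latent-variable count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DegenerateResponseError,
    NotFittedError,
    RankError,
    UndefinedCorrelationError,
)
from .preprocess import Scaler, fit_scaler

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-12


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error sqrt(sum((y - y_hat)^2) / n)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("y and y_hat must be equal-length, nonempty")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def correlation(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson product-moment correlation between measured and predicted."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("correlation needs two equal-length vectors, n >= 2")
    dy = y - y.mean()
    dh = y_hat - y_hat.mean()
    denom = np.sqrt((dy**2).sum() * (dh**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in y or y_hat")
    return float(np.clip((dy * dh).sum() / denom, -1.0, 1.0))


@dataclass
class Metrics:
    """RMSE + Pearson r for one evaluation role."""

    rmse: float
    r: float
    n: int
    role: str  # calibration | cross-validation | prediction


@dataclass
class PLSModel:
    """Fitted PLS1 model on preprocessed data.

    ``weights`` (W), ``x_loadings`` (P) are p x n_lv; ``y_loadings`` (q) has
    one entry per component; ``regression_vector`` b satisfies y_hat = X b on
    preprocessed data. ``scores`` (T) are kept for diagnostics. ``scaler``
    and ``columns`` are optional attachments letting :func:`predict` map raw
    normalized intensities to original concentration units.
    """

    n_lv: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    scores: np.ndarray | None = None
    scaler: Scaler | None = None
    columns: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.regression_vector.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_lv": self.n_lv,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "columns": None if self.columns is None else self.columns.tolist(),
            "scaler": None
            if self.scaler is None
            else {
                "method": self.scaler.method,
                "column_means": self.scaler.column_means.tolist(),
                "column_sds": None
                if self.scaler.column_sds is None
                else self.scaler.column_sds.tolist(),
                "retained_columns": self.scaler.retained_columns.tolist(),
                "y_mean": self.scaler.y_mean,
                "y_sd": self.scaler.y_sd,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        scaler = None
        if d["scaler"] is not None:
            s = d["scaler"]
            scaler = Scaler(
                method=s["method"],
                column_means=np.asarray(s["column_means"]),
                column_sds=None if s["column_sds"] is None else np.asarray(s["column_sds"]),
                retained_columns=np.asarray(s["retained_columns"], dtype=np.int64),
                y_mean=s["y_mean"],
                y_sd=s["y_sd"],
            )
            scaler._fitted = True
        return cls(
            n_lv=d["n_lv"],
            weights=np.asarray(d["weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            regression_vector=np.asarray(d["regression_vector"]),
            columns=None if d["columns"] is None else np.asarray(d["columns"], dtype=np.int64),
            scaler=scaler,
        )


def _nipals(X: np.ndarray, y: np.ndarray, max_lv: int):
    """NIPALS PLS1 decomposition; may stop early on rank exhaustion.

    Returns (W, P, q, T) with as many components as were extractable.
    """
    Xd = X.copy()
    yd = y.astype(np.float64).copy()
    n, p = Xd.shape
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    T = np.zeros((n, max_lv))
    scale0 = np.linalg.norm(X) * np.linalg.norm(y) + _WEIGHT_TOL
    a = 0
    for a in range(max_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _WEIGHT_TOL * scale0:
            if a == 0:
                raise DegenerateResponseError("X carries no covariance with y")
            logger.debug("NIPALS stopped early at %d of %d components", a, max_lv)
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _WEIGHT_TOL:
            break
        pl = Xd.T @ t / tt
        ql = float(yd @ t / tt)
        Xd -= np.outer(t, pl)
        yd -= ql * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t
        a += 1
    return W[:, :a], P[:, :a], q[:a], T[:, :a]


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray, n_lv: int) -> np.ndarray:
    Wl, Pl, ql = W[:, :n_lv], P[:, :n_lv], q[:n_lv]
    # b = W (P'W)^{-1} q ; P'W is upper triangular with unit diagonal for PLS1
    return Wl @ np.linalg.solve(Pl.T @ Wl, ql)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with exactly n_lv latent variables.

    X and y must already be preprocessed (centered / scaled) consistently.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise RankError(f"n_lv={n_lv} exceeds min(n_samples-1, p)={min(n - 1, p)}")
    W, P, q, T = _nipals(X, y, n_lv)
    if W.shape[1] < n_lv:
        raise RankError(
            f"data supports only {W.shape[1]} components, {n_lv} requested"
        )
    return PLSModel(
        n_lv=n_lv,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=_regression_vector(W, P, q, n_lv),
        scores=T,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new rows.

    With an attached scaler (and optional column subset) X_new is taken as
    raw normalized intensities over the model's bin columns and the result
    comes back in original concentration units; otherwise X_new must be
    preprocessed like the training data and the scaled response is returned.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if model.scaler is not None:
        if model.columns is not None:
            X_new = X_new[:, model.columns]
        Xs = model.scaler.apply(X_new)
        if Xs.shape[1] != model.n_features:
            raise NotFittedError("scaler/model feature mismatch")
        return model.scaler.inverse_y(Xs @ model.regression_vector)
    if X_new.shape[1] != model.n_features:
        from .exceptions import AlignmentError

        raise AlignmentError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return X_new @ model.regression_vector


@dataclass
class CVResult:
    """Pooled Monte-Carlo cross-validation trace."""

    rmsecv_by_lv: dict[int, float]
    rcv_by_lv: dict[int, float]
    chosen_lv: int
    n_splits: int
    leave_out: int
    seed: int | None

    @property
    def rmsecv(self) -> float:
        return self.rmsecv_by_lv[self.chosen_lv]

    @property
    def rcv(self) -> float:
        return self.rcv_by_lv[self.chosen_lv]


def make_splits(
    n_samples: int,
    leave_out: int = 3,
    n_splits: int = 200,
    seed: int | None = 0,
) -> list[np.ndarray]:
    """Held-out index sets for Monte-Carlo CV.

    With ``leave_out == 1`` and ``n_splits == n_samples`` the splits are the
    exhaustive leave-one-out enumeration instead of random draws.
    """
    if not 0 < leave_out < n_samples:
        raise ValueError("leave_out must be in (0, n_samples)")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if leave_out == 1 and n_splits == n_samples:
        return [np.asarray([i]) for i in range(n_samples)]
    rng = np.random.default_rng(seed)
    return [
        rng.choice(n_samples, size=leave_out, replace=False) for _ in range(n_splits)
    ]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid,
    leave_out: int = 3,
    n_splits: int = 200,
    seed: int | None = 0,
    scaling: str | None = "autoscale",
    splits: list[np.ndarray] | None = None,
    lv_selection: str = "min",
) -> CVResult:
    """Monte-Carlo CV with random removal of ``leave_out`` samples.

    Preprocessing (column scaling) is refitted inside every split; held-out
    residuals are pooled across splits per LV. The chosen LV minimizes
    pooled RMSECV, ties broken toward fewer LVs; ``lv_selection="one_se"``
    instead picks the smallest LV whose RMSECV is within one standard error
    (delta method on the pooled squared residuals) of the minimum. A grid
    entry exceeding the rank available on some split is skipped (and
    logged) for that split.
    """
    if lv_selection not in ("min", "one_se"):
        raise ValueError("lv_selection must be 'min' or 'one_se'")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    lv_grid = sorted(set(int(a) for a in lv_grid))
    if not lv_grid or lv_grid[0] < 1:
        raise ValueError("lv_grid must contain positive integers")
    if splits is None:
        splits = make_splits(len(y), leave_out, n_splits, seed)
    max_lv = lv_grid[-1]
    pooled: dict[int, list[tuple[float, float]]] = {a: [] for a in lv_grid}
    for held in splits:
        train = np.setdiff1d(np.arange(len(y)), held)
        if scaling is None:
            Xtr, ytr = X[train], y[train]
            Xte = X[held]
            inverse = lambda v: v  # noqa: E731
        else:
            scaler = fit_scaler(X[train], y[train], method=scaling)
            Xtr = scaler.apply(X[train])
            ytr = scaler.transform_y(y[train])
            Xte = scaler.apply(X[held])
            inverse = scaler.inverse_y
        bound = min(Xtr.shape[0] - 1, Xtr.shape[1])
        try:
            W, P, q, _ = _nipals(Xtr, ytr, min(max_lv, bound))
        except DegenerateResponseError:
            logger.warning("degenerate split skipped entirely")
            continue
        avail = W.shape[1]
        for a in lv_grid:
            if a > avail:
                logger.debug("LV %d exceeds rank %d on a split; skipped", a, avail)
                continue
            b = _regression_vector(W, P, q, a)
            y_hat = inverse(Xte @ b)
            pooled[a].extend(zip(y[held].tolist(), np.atleast_1d(y_hat).tolist()))
    rmsecv_by_lv: dict[int, float] = {}
    rcv_by_lv: dict[int, float] = {}
    se_by_lv: dict[int, float] = {}
    for a, pairs in pooled.items():
        if not pairs:
            continue
        yy = np.asarray([p[0] for p in pairs])
        hh = np.asarray([p[1] for p in pairs])
        rmsecv_by_lv[a] = rmse(yy, hh)
        sq = (yy - hh) ** 2
        if sq.size > 1 and rmsecv_by_lv[a] > 0:
            # delta method: se(sqrt(MSE)) = se(MSE) / (2 sqrt(MSE))
            se_by_lv[a] = float(
                np.std(sq, ddof=1) / np.sqrt(sq.size) / (2 * rmsecv_by_lv[a])
            )
        else:
            se_by_lv[a] = 0.0
        try:
            rcv_by_lv[a] = correlation(yy, hh)
        except (UndefinedCorrelationError, ValueError):
            rcv_by_lv[a] = float("nan")
    if not rmsecv_by_lv:
        raise RankError("no LV in the grid was evaluable on any split")
    chosen = min(rmsecv_by_lv, key=lambda a: (rmsecv_by_lv[a], a))
    if lv_selection == "one_se":
        threshold = rmsecv_by_lv[chosen] + se_by_lv[chosen]
        chosen = min(a for a in rmsecv_by_lv if rmsecv_by_lv[a] <= threshold)
    return CVResult(
        rmsecv_by_lv=rmsecv_by_lv,
        rcv_by_lv=rcv_by_lv,
        chosen_lv=chosen,
        n_splits=len(splits),
        leave_out=leave_out,
        seed=seed,
    )
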