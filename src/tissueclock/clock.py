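"""Support-vector-regression age models and their evaluation.

The clock is an epsilon-SVR on the selected marker betas. Kernel, C,
epsilon (and gamma for the RBF kernel) are chosen by exhaustive grid
search under k-fold cross-validation scored by mean absolute deviation
(MAD), the criterion used to compare clock variants throughout. Linear
kernels consume raw beta values; the RBF kernel standardizes the marker
submatrix with training statistics stored inside the model.

Five evaluation metrics are reported: RMSE, MAD, Pearson's r, MAPE and
Theil's U. Theil's U is implemented as the ratio of the model RMSE to the
RMSE of the naive predictor that outputs the observed mean age, so U < 1
means the clock beats that baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from tissueclock.containers import BetaMatrix, ages_for

THEIL_VARIANT = "rmse(model)/rmse(mean-age baseline)"


class ClockError(ValueError):
    pass


def default_grid(n_markers: int) -> list[dict]:
    """The hyperparameter grid, ordered by the tie-breaking preference.

    Ties in CV MAD resolve to the earliest entry: linear before rbf, then
    smaller C, then smaller epsilon, then smaller gamma.
    """
    Cs = (0.1, 1.0, 10.0, 100.0)
    epsilons = (0.1, 0.5, 1.0, 2.0)
    grid: list[dict] = []
    for C in Cs:
        for eps in epsilons:
            grid.append({"kernel": "linear", "C": C, "epsilon": eps, "gamma": None})
    for C in Cs:
        for eps in epsilons:
            for g in (1.0 / max(n_markers, 1), "scale"):
                grid.append({"kernel": "rbf", "C": C, "epsilon": eps, "gamma": g})
    return grid


def _make_estimator(params: dict):
    svr = SVR(
        kernel=params["kernel"],
        C=params["C"],
        epsilon=params["epsilon"],
        **({"gamma": params["gamma"]} if params["kernel"] == "rbf" else {}),
    )
    if params["kernel"] == "rbf":
        return Pipeline([("scale", StandardScaler()), ("svr", svr)])
    return svr


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive CV grid search minimizing mean fold MAD.

    Returns the chosen parameter dict and the full score table. The
    k-fold partition is shuffled with ``seed`` and shared by all grid
    points, so scores are comparable and the search is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ClockError("k-fold CV needs k >= 2")
    if n < k:
        raise ClockError(f"cannot {k}-fold split {n} samples")
    if grid is None:
        grid = default_grid(X.shape[1])
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    rows = []
    for params in grid:
        fold_mads = []
        for train, test in folds:
            est = _make_estimator(params)
            est.fit(X[train], y[train])
            pred = est.predict(X[test])
            fold_mads.append(float(np.mean(np.abs(pred - y[test]))))
        rows.append({**params, "cv_mad": float(np.mean(fold_mads))})
    table = pd.DataFrame(rows)
    best_idx = int(table["cv_mad"].idxmin())  # idxmin keeps the first minimum
    best = dict(grid[best_idx])
    return best, table


@dataclass
class ClockModel:
    """A fitted tissue clock: marker list, SVR state, hyperparameters."""

    tissue: str
    marker_ids: list[str]
    kernel: str
    C: float
    epsilon: float
    gamma: float | str | None
    estimator: object
    cv_table: pd.DataFrame | None = None
    metrics: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClockModel":
        return joblib.load(path)


def train_clock(
    mat: BetaMatrix,
    samples: pd.DataFrame,
    marker_ids: Sequence[str],
    hyperparams: dict,
    tissue: str | None = None,
) -> ClockModel:
    """Fit the epsilon-SVR on the marker submatrix."""
    marker_ids = list(marker_ids)
    if not marker_ids:
        raise ClockError("marker_ids must be nonempty")
    absent = [m for m in marker_ids if m not in mat.probe_ids]
    if absent:
        raise ClockError(f"markers absent from matrix: {absent[:10]}")
    X = mat.values.loc[marker_ids].to_numpy().T
    y = ages_for(mat, samples)
    est = _make_estimator(hyperparams)
    est.fit(X, y)
    return ClockModel(
        tissue=tissue or str(samples["tissue"].iloc[0]),
        marker_ids=marker_ids,
        kernel=hyperparams["kernel"],
        C=hyperparams["C"],
        epsilon=hyperparams["epsilon"],
        gamma=hyperparams.get("gamma"),
        estimator=est,
    )


def predict_age(model: ClockModel, mat: BetaMatrix) -> pd.Series:
    """Predicted age in years for every sample column of ``mat``."""
    absent = [m for m in model.marker_ids if m not in mat.probe_ids]
    if absent:
        raise ClockError(f"markers absent from matrix: {absent[:10]}")
    if mat.shape[1] == 0:
        return pd.Series(dtype=float, name="predicted_age")
    X = mat.values.loc[model.marker_ids].to_numpy().T
    pred = model.estimator.predict(X)
    return pd.Series(pred, index=mat.sample_ids, name="predicted_age")


@dataclass
class Metrics:
    rmse: float
    mad: float
    pearson_r: float
    mape: float
    theil_u: float
    theil_variant: str = THEIL_VARIANT

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mad": self.mad,
            "pearson_r": self.pearson_r,
            "mape": self.mape,
            "theil_u": self.theil_u,
            "theil_variant": self.theil_variant,
        }


def evaluate(predicted, observed) -> Metrics:
    """All five regression metrics between predicted and observed ages.

    ``pearson_r`` is NaN (undefined) when either vector is constant;
    MAPE requires all observed ages nonzero.
    """
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if yhat.shape != y.shape:
        raise ClockError(f"length mismatch: {yhat.shape} vs {y.shape}")
    if y.size == 0:
        raise ClockError("cannot evaluate empty vectors")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mad = float(np.mean(np.abs(resid)))
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        r = math.nan
    else:
        r = float(np.corrcoef(yhat, y)[0, 1])
    if np.any(y == 0):
        raise ClockError("MAPE undefined: observed age of 0 present")
    mape = float(100.0 * np.mean(np.abs(resid) / np.abs(y)))
    naive_rmse = float(np.sqrt(np.mean((y.mean() - y) ** 2)))
    theil = 0.0 if rmse == 0 else (math.inf if naive_rmse == 0 else rmse / naive_rmse)
    return Metrics(rmse=rmse, mad=mad, pearson_r=r, mape=mape, theil_u=theil)
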