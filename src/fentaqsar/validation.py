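"""Regression metrics and leave-one-out cross-validation.

The reported statistics follow common QSAR practice: r² is the squared
Pearson correlation between observed and predicted activities (the fitted
1 - SSE/SST coefficient is additionally exposed as ``r2_fit``), q² is the
leave-one-out cross-validated determination coefficient
1 - PRESS/TSS, and the error metrics are MSE, MAE and MAPE (percent).
Note q² may legitimately fall below an external-test r² (the Kubinyi
paradox), so no ordering between them is ever assumed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = ["ModelMetrics", "regression_metrics", "loo_q2"]


@dataclass(frozen=True)
class ModelMetrics:
    r2: float | None
    mse: float
    mae: float
    mape: float
    r2_fit: float | None = None
    q2: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def __str__(self) -> str:
        def fmt(x):
            return "n/a" if x is None else f"{x:.4f}"

        return (
            f"r2={fmt(self.r2)} q2={fmt(self.q2)} mse={fmt(self.mse)} "
            f"mae={fmt(self.mae)} mape={fmt(self.mape)}% (n={self.n})"
        )


def regression_metrics(y: Sequence[float], yhat: Sequence[float]) -> ModelMetrics:
    """Compute r² (Pearson²), r2_fit (1-SSE/SST), MSE, MAE and MAPE (%).

    Requires equal-length vectors of at least 2 observations.  For constant
    observed values r² is undefined and reported as None with a warning.
    MAPE assumes strictly non-zero observed values (pKi in practice).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    mape = float(100.0 * np.mean(np.abs(resid / y)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant observed values: r2 undefined")
        r2 = r2_fit = None
    else:
        r2_fit = float(1.0 - np.sum(resid**2) / sst)
        if np.std(yhat) == 0.0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    return ModelMetrics(r2=r2, mse=mse, mae=mae, mape=mape, r2_fit=r2_fit, n=y.size)


def loo_q2(
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    X: Sequence,
    y: Sequence[float],
) -> tuple[float, float]:
    """Leave-one-out cross-validation: returns (q2, PRESS).

    ``fit_predict(X_train, y_train, X_held)`` must refit the model on the
    held-in data and return predictions for the held-out rows.  ``X`` may
    be a 2-D array or any indexable sequence of per-molecule inputs.  Every
    fold must succeed; a failing fold aborts the whole computation.

    q² = 1 - PRESS / Σ(yᵢ - ȳ)².
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("LOO needs at least 3 observations")
    is_array = isinstance(X, np.ndarray)
    press = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if is_array:
            X_tr, X_te = X[keep], X[~keep]
        else:
            X_tr = [X[j] for j in range(n) if keep[j]]
            X_te = [X[i]]
        pred = np.asarray(fit_predict(X_tr, y[keep], X_te), dtype=float).ravel()
        press += float((y[i] - pred[0]) ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant activities: q2 undefined")
    return 1.0 - press / tss, press
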