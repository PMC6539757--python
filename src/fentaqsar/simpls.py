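"""SIMPLS partial least squares regression (de Jong's direct algorithm).

SIMPLS computes PLS weight vectors directly from the deflated covariance
s = Xᶜᵀyᶜ rather than by deflating X itself.  For a univariate response
the algorithm is, per component:

    r  = s projected orthogonal to the span of previous loadings
    t  = Xᶜ r, normalized to unit length (r rescaled accordingly)
    p  = Xᶜᵀ t          (X loading)
    q  = yᶜᵀ t          (y loading)
    s  ← s - v vᵀ s      with v the orthonormalized loading

and the regression vector mapping centered x to centered ŷ is B = R qᵀ.
Scores t are mutually orthogonal by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "simpls_fit", "pls_predict", "select_components"]


@dataclass
class PLSModel:
    """Centered SIMPLS fit: weights, loadings and regression coefficients."""

    n_components: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    weights: np.ndarray  # R, (p, A): x-weights, t = Xc @ R
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    coef: np.ndarray  # B, (p,): yhat_c = xc @ B

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.weights

    def to_json_dict(self) -> dict:
        return {
            "format": "fentaqsar-pls-v1",
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PLSModel":
        if d.get("format") != "fentaqsar-pls-v1":
            raise ValueError("not a serialized PLS model")
        return cls(
            n_components=int(d["n_components"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
        )


def simpls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a univariate SIMPLS model with the requested component count.

    If ``n_components`` exceeds the rank of the centered X the fit is
    truncated at the rank with a warning.  A zero-variance y is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 training rows")
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.std(y) == 0.0:
        raise ValueError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc  # (p,)
    R, P, Q, V = [], [], [], []
    tol = 1e-12 * max(1.0, float(np.abs(s).max()))
    for _ in range(n_components):
        r = s.copy()
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-10 or np.linalg.norm(s) <= tol:
            warnings.warn(
                f"rank deficiency: truncating at {len(R)} components "
                f"(requested {n_components})"
            )
            break
        t /= tnorm
        r /= tnorm
        pvec = Xc.T @ t
        qval = float(yc @ t)
        # orthonormalize the loading against previous ones, deflate s
        v = pvec.copy()
        for vprev in V:
            v -= vprev * (vprev @ pvec)
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            warnings.warn(
                f"rank deficiency: truncating at {len(R)} components "
                f"(requested {n_components})"
            )
            break
        v /= vnorm
        s = s - v * (v @ s)
        R.append(r)
        P.append(pvec)
        Q.append(qval)
        V.append(v)

    if not R:
        raise ValueError("could not extract any PLS component (X has no variance)")
    Rm = np.column_stack(R)
    Pm = np.column_stack(P)
    qv = np.asarray(Q, dtype=float)
    coef = Rm @ qv
    return PLSModel(
        n_components=len(R),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=Rm,
        x_loadings=Pm,
        y_loadings=qv,
        coef=coef,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """ŷ = (x - x_mean)·B + y_mean for one row or a matrix of rows."""
    return model.predict(X)


def _coef_path(X: np.ndarray, y: np.ndarray, max_components: int) -> list[np.ndarray]:
    """Cumulative SIMPLS regression vectors B_1..B_A on centered data.

    Returns the list of coefficient vectors after 1, 2, ... components;
    the path stops early at the rank of Xc (callers reuse the last entry
    for higher counts, matching the truncation of :func:`simpls_fit`).
    """
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    yc = y - y.mean()
    s = Xc.T @ yc
    V: list[np.ndarray] = []
    coefs: list[np.ndarray] = []
    B = np.zeros(X.shape[1])
    tol = 1e-12 * max(1.0, float(np.abs(s).max()))
    for _ in range(max_components):
        r = s.copy()
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-10 or np.linalg.norm(s) <= tol:
            break
        t /= tnorm
        r /= tnorm
        pvec = Xc.T @ t
        q = float(yc @ t)
        v = pvec.copy()
        for vprev in V:
            v -= vprev * (vprev @ pvec)
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            break
        v /= vnorm
        s = s - v * (v @ s)
        V.append(v)
        B = B + r * q
        coefs.append(B.copy())
    return coefs


def loo_q2_profile(
    X: np.ndarray, y: np.ndarray, max_components: int
) -> dict[int, float]:
    """Leave-one-out q² for every component count 1..max_components.

    Each fold runs a single SIMPLS pass to the maximum count and predicts
    the held-out row at every count along the path, which is numerically
    identical to refitting per count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("LOO needs at least 3 observations")
    press = np.zeros(max_components)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        coefs = _coef_path(Xtr, ytr, max_components)
        if not coefs:
            raise ValueError("fold with no extractable component")
        xc = X[i] - Xtr.mean(axis=0)
        ym = ytr.mean()
        for a in range(max_components):
            B = coefs[min(a, len(coefs) - 1)]
            press[a] += (y[i] - (xc @ B + ym)) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    return {a + 1: 1.0 - press[a] / tss for a in range(max_components)}


def select_components(
    X: np.ndarray, y: np.ndarray, max_components: int = 10
) -> tuple[int, dict[int, float]]:
    """Pick the component count maximizing leave-one-out q².

    Returns ``(best, q2_by_count)``.  Ties go to the smaller count; if no
    count achieves q² > 0 the smallest count is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    max_components = max(min(max_components, X.shape[0] - 2), 1)
    q2_by_count = loo_q2_profile(X, y, max_components)
    best = max(q2_by_count, key=lambda a: (q2_by_count[a], -a))
    if q2_by_count[best] <= 0:
        warnings.warn("no component count achieves q2 > 0; returning the smallest")
        best = min(q2_by_count)
    return best, q2_by_count
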