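"""Distance-weighted k-nearest-neighbor regression on fingerprint distances.

The two 2D affinity models are kNN regressors over Tanimoto distances
between ECFP6-like / FCFP6-like circular fingerprints: a query's pKi is
the inverse-distance-weighted mean of its k nearest training compounds.
Exact structural matches (distance < 1e-9) short-circuit to the mean
activity of the matching training compounds.

The model/results split follows the usual statistical-modelling idiom:
``FingerprintKNN(table, ...)`` describes the model,
``.fit()`` returns a :class:`KNNResults` carrying the trained state,
diagnostics and ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .chemio import MoleculeTable
from .fingerprints import (
    DEFAULT_LENGTH,
    Fingerprint,
    distance,
    fingerprint,
)
from .validation import ModelMetrics, loo_q2, regression_metrics

__all__ = [
    "FingerprintKNN",
    "KNNResults",
    "fit_knn",
    "predict_knn",
    "select_k",
    "knn_predict_one",
]

ZERO_DISTANCE = 1e-9
WEIGHTINGS = ("inverse_distance", "uniform")


def knn_predict_one(
    distances: np.ndarray,
    activities: np.ndarray,
    k: int,
    weighting: str = "inverse_distance",
) -> float:
    """Predict from precomputed query-to-training distances.

    The k nearest neighbors are taken with ties broken by training order
    (stable argsort).  If any neighbor is an exact match (d < 1e-9) the
    prediction is the plain mean over all exact matches; otherwise the
    weighted mean with w = 1/d (or w = 1 for uniform weighting).
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(activities, dtype=float)
    order = np.argsort(d, kind="stable")[:k]
    dk, yk = d[order], y[order]
    exact = dk < ZERO_DISTANCE
    if exact.any():
        return float(yk[exact].mean())
    if weighting == "uniform":
        return float(yk.mean())
    w = 1.0 / dk
    return float((w * yk).sum() / w.sum())


@dataclass
class FingerprintKNN:
    """kNN regression model specification over a training molecule table."""

    train: MoleculeTable
    flavor: str = "ECFP6"
    k: int = 5
    weighting: str = "inverse_distance"
    length: int = DEFAULT_LENGTH

    def __post_init__(self):
        if len(self.train) == 0:
            raise ValueError("empty training table")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not 1 <= self.k <= len(self.train):
            raise ValueError(
                f"k must be in [1, {len(self.train)}], got {self.k}"
            )

    def fit(self, compute_q2: bool = False) -> "KNNResults":
        fps = [fingerprint(r, self.flavor, self.length) for r in self.train]
        res = KNNResults(
            model=self,
            fingerprints=fps,
            activities=self.train.pki,
            ids=self.train.ids,
        )
        if compute_q2:
            res.q2  # noqa: B018 - force cached computation
        return res


class KNNResults:
    """Fitted kNN model: stored neighbors plus prediction and diagnostics."""

    def __init__(self, model, fingerprints, activities, ids):
        self.model = model
        self.fingerprints: list[Fingerprint] = fingerprints
        self.activities = np.asarray(activities, dtype=float)
        self.ids = list(ids)
        self._q2 = None

    # -- prediction ---------------------------------------------------
    def _as_fingerprint(self, query) -> Fingerprint:
        if isinstance(query, Fingerprint):
            if (
                query.flavor != self.model.flavor
                or query.length != self.model.length
            ):
                raise ValueError("query fingerprint flavor/length mismatch")
            return query
        return fingerprint(query, self.model.flavor, self.model.length)

    def distances_to_training(self, query) -> np.ndarray:
        q = self._as_fingerprint(query)
        return np.array([distance(q, fp) for fp in self.fingerprints])

    def predict_one(self, query) -> float:
        return knn_predict_one(
            self.distances_to_training(query),
            self.activities,
            self.model.k,
            self.model.weighting,
        )

    def predict(self, queries) -> np.ndarray:
        if isinstance(queries, (Fingerprint, str)) or hasattr(queries, "mol"):
            queries = [queries]
        return np.array([self.predict_one(q) for q in queries])

    def max_similarity(self, query) -> float:
        """Largest Tanimoto similarity of the query to any training compound."""
        return float(1.0 - self.distances_to_training(query).min())

    def predict_with_similarity(self, query) -> tuple[float, float]:
        """(prediction, max training similarity) from one distance pass."""
        d = self.distances_to_training(query)
        pred = knn_predict_one(d, self.activities, self.model.k, self.model.weighting)
        return pred, float(1.0 - d.min())

    # -- diagnostics ---------------------------------------------------
    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.fingerprints)

    @property
    def q2(self) -> float:
        """Leave-one-out q² of the stored training set."""
        if self._q2 is None:
            self._q2, _ = self._loo()
        return self._q2

    def _loo(self) -> tuple[float, float]:
        n = len(self.fingerprints)
        D = self._training_distance_matrix()
        preds = np.empty(n)
        k = min(self.model.k, n - 1)
        for i in range(n):
            keep = np.arange(n) != i
            preds[i] = knn_predict_one(
                D[i, keep], self.activities[keep], k, self.model.weighting
            )
        tss = float(np.sum((self.activities - self.activities.mean()) ** 2))
        press = float(np.sum((self.activities - preds) ** 2))
        return 1.0 - press / tss, press

    def _training_distance_matrix(self) -> np.ndarray:
        n = len(self.fingerprints)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = distance(
                    self.fingerprints[i], self.fingerprints[j]
                )
        return D

    def metrics(self, table: MoleculeTable) -> ModelMetrics:
        preds = self.predict(list(table))
        m = regression_metrics(table.pki, preds)
        return m

    def summary(self) -> str:
        m = self.model
        lines = [
            f"kNN regression ({m.flavor}, fold length {m.length})",
            f"  k = {m.k}, weighting = {m.weighting}",
            f"  n_train = {len(self.ids)}, "
            f"pKi range [{self.activities.min():.2f}, {self.activities.max():.2f}]",
            f"  LOO q2 = {self.q2:.4f}",
        ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "format": "fentaqsar-knn-v1",
            "flavor": self.model.flavor,
            "length": self.model.length,
            "k": self.model.k,
            "weighting": self.model.weighting,
            "ids": self.ids,
            "bits": [list(fp.sorted_bits) for fp in self.fingerprints],
            "activities": self.activities.tolist(),
        }

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path) -> "KNNResults":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format") != "fentaqsar-knn-v1":
            raise ValueError("not a serialized kNN model")
        fps = [
            Fingerprint(frozenset(b), length=d["length"], flavor=d["flavor"])
            for b in d["bits"]
        ]
        model = FingerprintKNN.__new__(FingerprintKNN)
        model.train = None  # detached from the original table
        model.flavor = d["flavor"]
        model.length = d["length"]
        model.k = d["k"]
        model.weighting = d["weighting"]
        return cls(model, fps, np.asarray(d["activities"]), d["ids"])


# -- functional aliases mirroring the operation-style API ---------------


def fit_knn(
    train: MoleculeTable,
    flavor: str = "ECFP6",
    k: int = 5,
    weighting: str = "inverse_distance",
    length: int = DEFAULT_LENGTH,
) -> KNNResults:
    return FingerprintKNN(train, flavor=flavor, k=k, weighting=weighting, length=length).fit()


def predict_knn(model: KNNResults, query) -> float:
    return model.predict_one(query)


def select_k(
    train: MoleculeTable,
    flavor: str = "ECFP6",
    k_grid=(1, 2, 3, 5, 7, 10),
    weighting: str = "inverse_distance",
    length: int = DEFAULT_LENGTH,
) -> tuple[int, dict[int, float]]:
    """Choose k from a grid by maximizing leave-one-out q² (ties → smallest k)."""
    k_grid = [k for k in k_grid if 1 <= k <= len(train) - 1]
    if not k_grid:
        raise ValueError("empty or infeasible k grid")
    base = FingerprintKNN(train, flavor=flavor, k=1, weighting=weighting, length=length).fit()
    q2_by_k: dict[int, float] = {}
    for k in sorted(set(k_grid)):
        res = KNNResults(
            FingerprintKNN(train, flavor=flavor, k=k, weighting=weighting, length=length),
            base.fingerprints,
            base.activities,
            base.ids,
        )
        q2_by_k[k] = res.q2
    best = max(q2_by_k, key=lambda k: (q2_by_k[k], -k))
    return best, q2_by_k


def fit_fingerprint_pls(
    train: MoleculeTable,
    flavor: str = "FCFP6",
    n_components: int = 2,
    length: int = DEFAULT_LENGTH,
):
    """Experimental: SIMPLS regression on the folded fingerprint bit matrix.

    Provided for parity with field-based PLS; the supported 2D models are
    the kNN regressors.  Returns (PLSModel, bit-matrix builder).
    """
    from .simpls import simpls_fit

    fps = [fingerprint(r, flavor, length) for r in train]

    def to_matrix(fingerprint_list) -> np.ndarray:
        X = np.zeros((len(fingerprint_list), length))
        for i, fp in enumerate(fingerprint_list):
            X[i, list(fp.bits)] = 1.0
        return X

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = simpls_fit(to_matrix(fps), train.pki, n_components)
    return model, to_matrix
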