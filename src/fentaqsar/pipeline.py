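"""High-level workflow helpers shared by the CLI, tests and scripts.

Wires the standard run together: split a molecule table, fit the three
affinity models (field-based SIMPLS plus ECFP6/FCFP6 kNN), produce a
metrics report per partition, and score arbitrary molecule lists with the
gated consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemio import MoleculeTable, split_train_test
from .enumeration import consensus_predict
from .field import FieldQSAR, FieldQSARResults
from .knn import FingerprintKNN, KNNResults
from .validation import regression_metrics

logger = logging.getLogger(__name__)

__all__ = ["TrainedModels", "train_models", "metrics_report", "predict_consensus"]


@dataclass
class TrainedModels:
    field: FieldQSARResults
    ecfp6: KNNResults
    fcfp6: KNNResults

    def summary(self) -> str:
        return "\n\n".join(
            [self.field.summary(), self.ecfp6.summary(), self.fcfp6.summary()]
        )


def train_models(
    table: MoleculeTable,
    seed: int = 1,
    n_test: int | None = None,
    k: int = 5,
    length: int = 2048,
    weighting: str = "inverse_distance",
    spacing: float = 1.0,
    margin: float = 4.0,
    minimize: bool = True,
    max_components: int = 10,
    n_components: int | None = None,
) -> tuple[MoleculeTable, TrainedModels]:
    """Split a table (unless already partitioned) and fit all three models."""
    if not len(table.train) or not len(table.test):
        table = split_train_test(table, n_test=n_test, seed=seed)
    train = table.train
    logger.info("training on %d molecules, %d held out", len(train), len(table.test))
    field = FieldQSAR(
        train,
        spacing=spacing,
        margin=margin,
        minimize=minimize,
        seed=seed,
        max_components=max_components,
    ).fit(n_components=n_components)
    ecfp = FingerprintKNN(train, flavor="ECFP6", k=k, weighting=weighting, length=length).fit()
    fcfp = FingerprintKNN(train, flavor="FCFP6", k=k, weighting=weighting, length=length).fit()
    return table, TrainedModels(field=field, ecfp6=ecfp, fcfp6=fcfp)


def metrics_report(models: TrainedModels, table: MoleculeTable) -> pd.DataFrame:
    """Training/test metrics for each model, one row per (model, partition).

    Training rows carry the LOO q2; the field-model training row uses the
    fitted values on the descriptor matrix (so excluded molecules are
    absent by construction).
    """
    rows = []
    train, test = table.train, table.test

    field_train = regression_metrics(models.field.y, models.field.fittedvalues)
    rows.append(("3D-field", "train", field_train, models.field.q2))
    rows.append(("3D-field", "test", models.field.metrics(test), None))
    for name, res in (("ECFP6 kNN", models.ecfp6), ("FCFP6 kNN", models.fcfp6)):
        rows.append((name, "train", res.metrics(train), res.q2))
        rows.append((name, "test", res.metrics(test), None))

    return pd.DataFrame(
        [
            {
                "model": name,
                "partition": part,
                "n": m.n,
                "r2": m.r2,
                "q2": q2,
                "mse": m.mse,
                "mae": m.mae,
                "mape": m.mape,
            }
            for name, part, m, q2 in rows
        ]
    )


def predict_consensus(
    models: TrainedModels, table: MoleculeTable, seed: int = 0, minimize: bool = False
) -> pd.DataFrame:
    """Gated consensus predictions for an arbitrary molecule table."""
    rows = [
        consensus_predict(
            rec, models.field, models.ecfp6, models.fcfp6, seed=seed, minimize=minimize
        ).as_row()
        for rec in table
    ]
    return pd.DataFrame(rows)
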