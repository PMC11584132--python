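"""Imputation quality metrics and the downstream-classification harness.

Three quantities summarise an imputation experiment:

* **RMSE over missing cells** — root mean squared error restricted to the
  amputated positions, computed on the min-max-normalized scale so columns
  with different units contribute comparably.  Observed cells never enter.
* **PFC** (proportion falsely classified) — among missing cells of binary
  and nominal columns, the fraction filled with the wrong category; it is
  evaluated after attribute projection, where categories exist.
* **AUC** of a downstream classifier trained on the completed table,
  measuring how much of the label signal imputation preserved.

ROC/AUC computations delegate to scikit-learn; ties receive the
half-credit Mann-Whitney convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .table import (
    AttributeVector,
    MaskMatrix,
    MixedTypeTable,
    NOMINAL,
    REAL,
    infer_attributes,
)

__all__ = [
    "MetricError",
    "EvalReport",
    "rmse_missing",
    "pfc",
    "roc_curve",
    "auc",
    "downstream_auc",
    "aggregate_reports",
]


class MetricError(ValueError):
    """The metric is undefined for the supplied inputs."""


@dataclass
class EvalReport:
    """One experiment's scores plus the per-seed values behind them."""

    rmse: float
    pfc: float | None
    auc: float | None
    n_missing_cells: int
    n_missing_categorical: int
    per_seed_values: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise MetricError("rmse must be nonnegative")
        for name in ("pfc", "auc"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise MetricError(f"{name} must lie in [0, 1]")


def _mask_array(m) -> np.ndarray:
    return m.m if isinstance(m, MaskMatrix) else np.asarray(m)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, MixedTypeTable) else np.asarray(x, dtype=float)


def rmse_missing(x_true_norm, x_imp_norm, m) -> float:
    """RMSE restricted to missing cells, both matrices normalized."""
    xt, xi, mm = _values(x_true_norm), _values(x_imp_norm), _mask_array(m)
    if not (xt.shape == xi.shape == mm.shape):
        raise MetricError("shapes disagree")
    miss = mm == 0
    if not miss.any():
        raise MetricError("no missing cells: RMSE over missing cells undefined")
    return float(np.sqrt(np.mean((xt[miss] - xi[miss]) ** 2)))


def pfc(x_true, x_imp, m, a: AttributeVector) -> float:
    """Fraction of missing categorical cells filled with the wrong category."""
    xt, xi, mm = _values(x_true), _values(x_imp), _mask_array(m)
    cat = np.isin(a.codes, (1, 2))
    miss = (mm == 0) & cat[None, :]
    n_a = int(miss.sum())
    if n_a == 0:
        raise MetricError("no missing categorical cells: PFC undefined")
    wrong = int((xt[miss] != xi[miss]).sum())
    return wrong / n_a


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise MetricError("labels must contain both classes 0 and 1")
    return labels


def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """ROC staircase as (FPR, TPR) points from (0, 0) to (1, 1)."""
    labels = _check_labels(labels)
    fpr, tpr, _ = _skm.roc_curve(labels, np.asarray(scores, dtype=float),
                                 drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties get 1/2)."""
    labels = _check_labels(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def downstream_auc(x_imp, labels, folds: int = 5, seed: int = 0,
                   attributes: AttributeVector | None = None) -> float:
    """Pooled out-of-fold AUC of a regularized linear classifier.

    Nominal columns are one-hot encoded, real columns standardized, binary
    columns passed through; the classifier is L2-regularized logistic
    regression under stratified ``folds``-fold cross-validation.  The
    absolute value depends on this classifier choice; across imputers on
    the same data the ordering is the quantity of interest.
    """
    labels = _check_labels(labels)
    table = (
        x_imp
        if isinstance(x_imp, MixedTypeTable)
        else MixedTypeTable(
            np.asarray(x_imp, dtype=float),
            [f"x{j}" for j in range(np.asarray(x_imp).shape[1])],
        )
    )
    if table.n_missing:
        raise MetricError("downstream classification needs a complete table")
    attrs = attributes or infer_attributes(table)
    X = table.values
    nominal = np.flatnonzero(attrs.codes == NOMINAL)
    real = np.flatnonzero(attrs.codes == REAL)
    binary = np.flatnonzero(attrs.codes == 1)
    pre = ColumnTransformer(
        [
            ("onehot", OneHotEncoder(handle_unknown="ignore"), nominal),
            ("scale", StandardScaler(), real),
            ("pass", "passthrough", binary),
        ]
    )
    clf = Pipeline(
        [("pre", pre), ("lr", LogisticRegression(C=1.0, max_iter=1000))]
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(labels))
    for train_idx, test_idx in skf.split(X, labels):
        clf.fit(X[train_idx], labels[train_idx])
        scores[test_idx] = clf.decision_function(X[test_idx])
    return auc(scores, labels)


def aggregate_reports(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- standard deviation over repeated seeds.

    ``rows`` is the tidy result table (one row per method x rate x seed);
    the output has one row per method x rate with ``<metric>_mean`` and
    ``<metric>_std`` columns, mirroring how repeated benchmark runs are
    reported.
    """
    metrics_cols = [c for c in ("rmse", "pfc", "auc") if c in rows.columns]
    grouped = rows.groupby(["method", "rate"])[metrics_cols]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
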