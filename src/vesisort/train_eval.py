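"""Training and evaluation of vesicle classifiers.

Label encoding follows the published convention: D (dense core) becomes
-1, E (error / non-assignable) rows are dropped, and every other code —
C (clear core) and N (non-determinable, shown to behave like CCVs) —
becomes +1.  DCV is the positive class of all DCV-specific metrics.

Cross-validation is leave-one-file-out: each source table (one tomogram's
CSV) is held out once as validation data while all others train the
classifier; standardization parameters come from the training folds only.
Numerical fitting of SVM / random forest / KNN delegates to scikit-learn;
confusion counting and the precision/recall/F arithmetic are native, and a
trained linear SVM is exportable as a :class:`LinearClassifierModel` for
the application-side classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .classifier import FEATURE_ORDER, LinearClassifierModel

__all__ = [
    "EncodedDataset",
    "TrainingConfig",
    "TrainedModel",
    "ConfusionCounts",
    "EvalReport",
    "encode_labels",
    "train",
    "confusion_counts",
    "compute_metrics",
    "leave_one_file_out_cv",
]

CCV_CODE = 1
DCV_CODE = -1


@dataclass
class EncodedDataset:
    """Feature matrix, +-1 labels and per-row group (source file) ids."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if not set(np.unique(self.y)) <= {CCV_CODE, DCV_CODE}:
            raise ValueError("labels must be +1 (CCV) or -1 (DCV)")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")


@dataclass
class TrainingConfig:
    """Algorithm choice and hyperparameters.

    Published settings: linear SVM with C = 1; random forest with t = 10 or
    t = 1500 bootstrap trees and probability-weighted voting; KNN with 10
    neighbors, uniform weights and Euclidean distance.
    """

    algorithm: str = "svm_linear"
    C: float = 1.0
    n_trees: int = 10
    k_neighbors: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in {"svm_linear", "svm_rbf", "random_forest", "knn"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.C <= 0 or self.n_trees <= 0 or self.k_neighbors <= 0:
            raise ValueError("hyperparameters must be positive")


def encode_labels(tables: list[pd.DataFrame],
                  sources: list[str] | None = None) -> EncodedDataset:
    """Concatenate feature tables into an encoded training dataset.

    D -> -1; E rows removed; C and N -> +1.  The group id of each row is
    its source table (``table.attrs["source"]`` unless ``sources`` given).
    """
    frames, ys, groups = [], [], []
    for i, table in enumerate(tables):
        src = (sources[i] if sources is not None
               else table.attrs.get("source", f"table{i}"))
        labels = table["label"].astype(str).str.strip()
        unknown = ~labels.isin(["C", "D", "N", "E"])
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValueError(
                f"unknown label code {labels.iloc[row]!r} at row {row} of {src}")
        keep = labels != "E"
        sub = table.loc[keep, list(FEATURE_ORDER)].astype(float)
        frames.append(sub)
        ys.append(np.where(labels[keep] == "D", DCV_CODE, CCV_CODE))
        groups.append(np.full(keep.sum(), src, dtype=object))
    X = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=list(FEATURE_ORDER))
    y = np.concatenate(ys) if ys else np.empty(0, dtype=int)
    g = np.concatenate(groups) if groups else np.empty(0, dtype=object)
    return EncodedDataset(X=X, y=y, groups=g)


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its standardization parameters."""

    config: TrainingConfig
    mu: np.ndarray
    sigma: np.ndarray
    estimator: object
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict +-1 labels for raw (unstandardized) features."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_order)].to_numpy(dtype=float)
        z = (np.asarray(X, dtype=float) - self.mu) / self.sigma
        return np.asarray(self.estimator.predict(z), dtype=int)

    def to_linear_model(self) -> LinearClassifierModel:
        """Export a trained linear SVM as a plain-number classifier model.

        sklearn's decision function is f(z) = w.z + intercept with f > 0
        mapping to class +1 (CCV); the exported hyperplane constant is
        b = -intercept so that margin = w.z - b = f(z).
        """
        if self.config.algorithm != "svm_linear":
            raise ValueError("only a linear SVM is exportable as a linear model")
        w = np.asarray(self.estimator.coef_).ravel()
        intercept = float(np.asarray(self.estimator.intercept_).ravel()[0])
        return LinearClassifierModel(
            mu=tuple(self.mu), sigma=tuple(self.sigma),
            weights=tuple(w), b=-intercept,
            feature_order=self.feature_order)


def train(dataset: EncodedDataset, config: TrainingConfig | None = None
          ) -> TrainedModel:
    """Standardize the training data and fit the configured classifier."""
    config = config or TrainingConfig()
    X = dataset.X[list(FEATURE_ORDER)].to_numpy(dtype=float)
    y = dataset.y
    if len(X) == 0:
        raise ValueError("empty training set")
    if config.algorithm.startswith("svm") and len(np.unique(y)) < 2:
        raise ValueError("SVM training needs at least one example of each class")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    sigma = np.where(sigma > 0, sigma, 1.0)  # guard constant features
    z = (X - mu) / sigma
    if config.algorithm == "svm_linear":
        est = SVC(kernel="linear", C=config.C, decision_function_shape="ovr")
    elif config.algorithm == "svm_rbf":
        est = SVC(kernel="rbf", C=config.C, decision_function_shape="ovr")
    elif config.algorithm == "random_forest":
        est = RandomForestClassifier(n_estimators=config.n_trees, bootstrap=True,
                                     random_state=config.seed)
    else:
        est = KNeighborsClassifier(n_neighbors=config.k_neighbors,
                                   weights="uniform", p=2)
    est.fit(z, y)
    return TrainedModel(config=config, mu=mu, sigma=sigma, estimator=est)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """DCV-positive confusion counts (DCV is the minority class of interest)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count tp/fp/fn/tn with DCV (-1) as the positive class."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("prediction length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((t == DCV_CODE) & (p == DCV_CODE))),
        fp=int(np.sum((t == CCV_CODE) & (p == DCV_CODE))),
        fn=int(np.sum((t == DCV_CODE) & (p == CCV_CODE))),
        tn=int(np.sum((t == CCV_CODE) & (p == CCV_CODE))),
    )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy plus DCV-specific precision, recall and F-score.

    precision = tp/(tp+fp), recall = tp/(tp+fn), F = 2PR/(P+R); a zero
    denominator yields NaN (the metric is undefined and excluded from fold
    averages).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    accuracy = (tp + tn) / total if total else math.nan
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f_score = math.nan
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision_DCV": precision,
            "recall_DCV": recall, "F_DCV": f_score}


@dataclass
class EvalReport:
    """Per-fold confusion counts and metrics with mean +- SD summaries."""

    folds: list[dict] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and sample SD (ddof=1) of each metric across folds.

        Folds where a metric is undefined (NaN) are excluded from that
        metric's average.
        """
        out = {}
        for key in ("accuracy", "precision_DCV", "recall_DCV", "F_DCV"):
            vals = np.array([f["metrics"][key] for f in self.folds], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                out[key] = (math.nan, math.nan)
            else:
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
                out[key] = (float(vals.mean()), sd)
        return out

    def to_dict(self) -> dict:
        return {
            "folds": [
                {"source": f["source"],
                 "counts": {"tp": f["counts"].tp, "fp": f["counts"].fp,
                            "fn": f["counts"].fn, "tn": f["counts"].tn},
                 "metrics": f["metrics"]}
                for f in self.folds
            ],
            "summary": {k: {"mean": m, "sd": s}
                        for k, (m, s) in self.summary().items()},
        }


def leave_one_file_out_cv(tables: list[pd.DataFrame],
                          config: TrainingConfig | None = None,
                          sources: list[str] | None = None) -> EvalReport:
    """Leave-one-file-out cross-validation over source feature tables.

    One fold per input file: the file's rows form the validation set, all
    other files are concatenated as training data, and standardization
    uses the training folds only.
    """
    if len(tables) < 2:
        raise ValueError("cross-validation needs at least 2 feature files")
    config = config or TrainingConfig()
    data = encode_labels(tables, sources)
    report = EvalReport()
    for src in pd.unique(data.groups):
        val = data.groups == src
        train_ds = EncodedDataset(X=data.X.loc[~val].reset_index(drop=True),
                                  y=data.y[~val], groups=data.groups[~val])
        model = train(train_ds, config)
        y_pred = model.predict(data.X.loc[val])
        counts = confusion_counts(data.y[val], y_pred)
        report.folds.append({"source": str(src), "counts": counts,
                             "metrics": compute_metrics(counts),
                             "mu": model.mu.copy(), "sigma": model.sigma.copy()})
    return report
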