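"""The shipped standardized linear decision rule for CCV vs DCV.

The classifier is a linear SVM exported as plain numbers: per-feature
standardization means and SDs, four weights and a hyperplane constant.  A
vesicle with standardized features z is scored by the signed margin

    m = w . z - b        (b = -4.36 for the shipped model)

and assigned CCV for m > 0 (ties included), DCV for m < 0.  With the
shipped parameters the decision hyperplane is

    -4.36 = -1.69*r + 1.65*gv - 0.76*distAZ + 1.21*GVSD

in standardized feature space.  The intercept is folded into the margin
(m = w.z + 4.36), so the all-means vector scores m = 4.36, on the CCV side.

gv is density-oriented throughout (electron-dense = numerically larger);
an optional gv offset aligns the darkest vesicle of a tomogram onto a
reference level before standardization, compensating brightness drift
between tomograms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import apply_gv_offset

__all__ = [
    "FEATURE_ORDER",
    "LinearClassifierModel",
    "default_model",
    "standardize",
    "unstandardize",
    "decision_margin",
    "classify_table",
]

#: fixed feature order of the model parameters
FEATURE_ORDER = ("r", "gv", "distAZ", "GVSD")


@dataclass
class LinearClassifierModel:
    """Standardization parameters plus linear weights and hyperplane constant."""

    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    weights: tuple[float, ...]
    b: float
    feature_order: tuple[str, ...] = FEATURE_ORDER
    gv_offset_threshold: float | None = None

    def __post_init__(self) -> None:
        n = len(self.feature_order)
        for name in ("mu", "sigma", "weights"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != n:
                raise ValueError(f"{name} must have {n} entries")
            setattr(self, name, vals)
        if any(s <= 0 for s in self.sigma):
            raise ValueError("all standardization SDs must be positive")
        self.feature_order = tuple(self.feature_order)
        self.b = float(self.b)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["feature_order"] = list(self.feature_order)
        for k in ("mu", "sigma", "weights"):
            data[k] = list(data[k])
        Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "LinearClassifierModel":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def default_model(gv_offset_threshold: float | None = None) -> LinearClassifierModel:
    """The shipped pre-trained model, exactly as published."""
    return LinearClassifierModel(
        mu=(10.4, 129.1, 259.1, 5.9),
        sigma=(3.1, 4.7, 118.5, 1.7),
        weights=(-1.69, 1.65, -0.76, 1.21),
        b=-4.36,
        gv_offset_threshold=gv_offset_threshold,
    )


def standardize(x: np.ndarray, mu, sigma) -> np.ndarray:
    """z = (x - mu) / sigma per feature (broadcasts over rows)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("standardization SDs must be positive")
    return (np.asarray(x, dtype=float) - mu) / sigma


def unstandardize(z: np.ndarray, mu, sigma) -> np.ndarray:
    return np.asarray(z, dtype=float) * np.asarray(sigma, dtype=float) \
        + np.asarray(mu, dtype=float)


def decision_margin(z: np.ndarray, model: LinearClassifierModel) -> np.ndarray:
    """Signed margin m = w.z - b; m = 0 on the decision hyperplane.

    ``z`` must be standardized and in the model's feature order; accepts a
    single vector or an (n, 4) matrix.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    w = np.asarray(model.weights, dtype=float)
    if z.shape[1] != len(w):
        raise ValueError(f"expected {len(w)} features, got {z.shape[1]}")
    m = z @ w - model.b
    return m if m.size > 1 else float(m[0])


def classify_table(table: pd.DataFrame, model: LinearClassifierModel | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every vesicle of a feature table.

    Applies the model's gv offset (if configured), standardizes, computes
    the margin and assigns CCV for margin >= 0 (ties go to the majority
    class), DCV otherwise.  Returns the table with ``margin`` and ``class``
    columns plus per-class counts.
    """
    model = model or default_model()
    missing = [f for f in model.feature_order if f not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing column(s) {missing}")
    out = table.copy()
    if out.empty:
        out["margin"] = pd.Series(dtype=float)
        out["class"] = pd.Series(dtype=str)
        return out, {"CCV": 0, "DCV": 0}
    bad = out[list(model.feature_order)].isna().any(axis=1)
    if bad.any():
        ids = (out.loc[bad, "id"].tolist() if "id" in out.columns
               else out.index[bad].tolist())
        raise ValueError(f"missing feature value(s) for vesicle(s) {ids}")
    shifted = apply_gv_offset(out, model.gv_offset_threshold)
    x = shifted[list(model.feature_order)].to_numpy(dtype=float)
    z = standardize(x, model.mu, model.sigma)
    margin = np.atleast_1d(decision_margin(z, model))
    out["margin"] = margin
    out["class"] = np.where(margin >= 0.0, "CCV", "DCV")
    counts = {"CCV": int((out["class"] == "CCV").sum()),
              "DCV": int((out["class"] == "DCV").sum())}
    return out, counts
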