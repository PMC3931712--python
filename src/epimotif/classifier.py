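"""Logistic regression classifier mapping features to binding probabilities.

The model is the standard sigmoid hypothesis h_theta(x) = g(theta^T x) with
g(z) = 1 / (1 + exp(-z)), fitted by minimizing the (unregularized, by
default) binary cross-entropy cost

    J(theta) = -(1/m) sum_i [ y_i ln h(x_i) + (1 - y_i) ln(1 - h(x_i)) ]

with a quasi-Newton unconstrained minimizer (BFGS), starting from theta = 0.
J is convex, so the optimum does not depend on the initialization.

Features are z-score standardized before fitting; the training mean and
standard deviation are stored on the model and applied identically at
prediction time.  Raw genomic distances span many orders of magnitude, so
fitting on unstandardized features would be badly conditioned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "sigmoid",
    "cost",
    "TrainingSet",
    "LRCModel",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]


def sigmoid(z):
    """Numerically stable logistic function 1 / (1 + exp(-z))."""
    return expit(z)


def cost(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
         l2: float = 0.0) -> tuple[float, np.ndarray]:
    """Cross-entropy cost and its gradient.

    ``X`` must already be standardized and intercept-augmented (first
    column of ones); ``theta[0]`` is the intercept and is never penalized.

    Uses the identity ln(1 + e^z) = logaddexp(0, z) so the cost stays
    finite for arbitrarily large |z|.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[0]
    if m == 0:
        raise ValueError("cost undefined for zero training examples")
    z = X @ theta
    # -[y ln h + (1-y) ln(1-h)] = logaddexp(0, z) - y z
    J = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = X.T @ (expit(z) - y) / m
    if l2 > 0.0:
        pen = np.concatenate([[0.0], theta[1:]])
        J += l2 / (2 * m) * float(pen @ pen)
        grad = grad + l2 / m * pen
    return J, grad


@dataclass
class TrainingSet:
    """Feature matrix and binary labels (1 = binding region)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (m, d) with one label per row")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one feature name per column required")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")


@dataclass
class LRCModel:
    """A fitted logistic regression classifier.

    ``theta`` has length d + 1 with the intercept first; ``mean`` and
    ``std`` are the training-set standardization statistics applied to
    incoming features before the linear map.
    """

    theta: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    feature_names: list[str]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        d = self.mean.size
        if self.theta.size != d + 1:
            raise ValueError("theta must have one entry per feature plus intercept")
        if np.any(self.std <= 0):
            raise ValueError("standard deviations of retained features must be > 0")


def train(
    ts: TrainingSet,
    l2: float = 0.0,
    gtol: float = 1e-6,
    max_iter: int = 500,
    theta0: np.ndarray | None = None,
) -> LRCModel:
    """Fit the classifier on a training set.

    Constant (zero-variance) features carry no information and would make
    standardization undefined; they are dropped with a warning.
    """
    X, y = ts.X, ts.y
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError(f"both classes required in training labels, got {classes}")
    if X.shape[0] < 2:
        raise ValueError("need at least two training examples")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    keep = std > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(ts.feature_names, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    if not np.any(keep):
        raise ValueError("all features are constant; nothing to fit")
    names = [n for n, k in zip(ts.feature_names, keep) if k]
    mean, std = mean[keep], std[keep]
    Z = (X[:, keep] - mean) / std
    A = np.hstack([np.ones((Z.shape[0], 1)), Z])

    x0 = np.zeros(A.shape[1]) if theta0 is None else np.asarray(theta0, float)
    res = minimize(
        cost,
        x0,
        args=(A, y.astype(float), l2),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    return LRCModel(
        theta=res.x,
        mean=mean,
        std=std,
        feature_names=names,
        training_meta={
            "m": int(X.shape[0]),
            "final_cost": float(res.fun),
            "converged": bool(res.success),
            "n_iter": int(res.nit),
            "l2": float(l2),
        },
    )


def _standardized_design(model: LRCModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.mean.size} features)"
        )
    Z = (X - model.mean) / model.std
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


def predict_proba(model: LRCModel, X: np.ndarray) -> np.ndarray:
    """Binding probability for one feature vector or a (m, d) matrix."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    p = expit(_standardized_design(model, X) @ model.theta)
    return float(p[0]) if single else p


def save_model(model: LRCModel, path: str | Path) -> None:
    doc = {
        "format": "epimotif-lrc-1",
        "theta": model.theta.tolist(),
        "mean": model.mean.tolist(),
        "std": model.std.tolist(),
        "feature_names": model.feature_names,
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> LRCModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "epimotif-lrc-1":
        raise ValueError(f"not a classifier model file: {path}")
    return LRCModel(
        theta=np.asarray(doc["theta"], dtype=float),
        mean=np.asarray(doc["mean"], dtype=float),
        std=np.asarray(doc["std"], dtype=float),
        feature_names=list(doc["feature_names"]),
        training_meta=dict(doc["training_meta"]),
    )
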