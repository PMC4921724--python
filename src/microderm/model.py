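"""Soft-margin SVM with RBF kernel for benign/malignant classification.

The classifier solves

    min_{w,b,xi}  1/2 w'w + C sum_i xi_i
    s.t.          y_i (w' phi(x_i) + b) >= 1 - xi_i,   xi_i >= 0

with labels y in {+1 (malignant), -1 (benign)} and the Gaussian kernel
K(x, x') = exp(-gamma ||x - x'||^2). The quadratic program is solved by an
established dual solver; the fitted model is stored explicitly (support
vectors, signed dual coefficients, bias) so the decision function
sum_i alpha_i y_i K(sv_i, x) + b is evaluated by this module and the model
round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureTable, ScalingParams, apply_scaling

__all__ = ["SvmConfig", "SvmModel", "rbf_kernel", "train", "predict", "tune", "DEFAULT_GRID"]


@dataclass(frozen=True)
class SvmConfig:
    C: float = 10.0
    gamma: float = 0.1

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


DEFAULT_GRID = tuple(
    SvmConfig(C=c, gamma=g) for c in (0.1, 1.0, 10.0, 100.0) for g in (0.01, 0.1, 1.0, 10.0)
)


def rbf_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> float | np.ndarray:
    """exp(-gamma ||a - b||^2); 1 iff a == b, decays to 0 with distance."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    out = np.exp(-gamma * d2)
    return float(out[0, 0]) if out.size == 1 else out


@dataclass
class SvmModel:
    """Explicit RBF-SVM: decision(x) = sum_i coef_i K(sv_i, x) + bias.

    ``scaling`` and ``subset`` record the preprocessing the training table
    went through so test vectors can be pushed through the same map.
    """

    support_vectors: np.ndarray       # n_sv x d
    dual_coef: np.ndarray             # signed alpha_i * y_i
    bias: float
    config: SvmConfig
    scaling: ScalingParams | None = None
    subset: tuple[str, ...] | None = None
    feature_names: tuple[str, ...] | None = field(default=None)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"expected {self.support_vectors.shape[1]} features, got {X.shape[1]}"
            )
        K = rbf_kernel(X, self.support_vectors, self.config.gamma)
        K = np.atleast_2d(K)
        return K @ self.dual_coef + self.bias

    def to_json(self, path) -> None:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.config.C,
            "gamma": self.config.gamma,
            "subset": list(self.subset) if self.subset else None,
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "scaling": None
            if self.scaling is None
            else {
                "min": self.scaling.minima.to_dict(),
                "max": self.scaling.maxima.to_dict(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SvmModel":
        with open(path) as fh:
            p = json.load(fh)
        scaling = None
        if p["scaling"] is not None:
            scaling = ScalingParams(
                minima=pd.Series(p["scaling"]["min"]), maxima=pd.Series(p["scaling"]["max"])
            )
        return cls(
            support_vectors=np.asarray(p["support_vectors"], dtype=float),
            dual_coef=np.asarray(p["dual_coef"], dtype=float),
            bias=float(p["bias"]),
            config=SvmConfig(C=p["C"], gamma=p["gamma"]),
            scaling=scaling,
            subset=tuple(p["subset"]) if p["subset"] else None,
            feature_names=tuple(p["feature_names"]) if p["feature_names"] else None,
        )


def train(
    table: FeatureTable,
    config: SvmConfig,
    scaling: ScalingParams | None = None,
    subset: tuple[str, ...] | None = None,
) -> SvmModel:
    """Fit the soft-margin RBF-SVM on an already scaled, subset-restricted
    table (labels 0/1 are mapped to -1/+1 internally)."""
    y01 = table.labels
    if len(np.unique(y01)) < 2:
        raise ValueError("training data must contain both classes")
    X = table.data.to_numpy(dtype=float)
    y = np.where(y01 == 1, 1, -1)
    clf = SVC(C=config.C, kernel="rbf", gamma=config.gamma)
    clf.fit(X, y)
    # sklearn orders classes_ ascending, so positive decision values mean +1
    assert list(clf.classes_) == [-1, 1]
    return SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        config=config,
        scaling=scaling,
        subset=subset,
        feature_names=tuple(table.names),
    )


def predict(
    model: SvmModel, vectors: FeatureTable | pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1 malignant / 0 benign) and decision values for new samples.

    When the model carries scaling/subset parameters they are applied first.
    A decision value of exactly 0 is assigned to the malignant class — the
    clinically fail-safe direction for a tie.
    """
    if isinstance(vectors, FeatureTable):
        vectors = vectors.data
    if isinstance(vectors, pd.DataFrame):
        if model.subset is not None:
            vectors = vectors[list(model.subset)]
        if model.scaling is not None:
            keep = list(vectors.columns)
            params = ScalingParams(
                minima=model.scaling.minima[keep], maxima=model.scaling.maxima[keep]
            )
            vectors = apply_scaling(vectors, params)
        X = vectors.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
    decision = model.decision_function(X)
    labels = (decision >= 0).astype(np.int64)  # ties -> malignant
    return labels, decision


def tune(
    table: FeatureTable,
    grid=DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
) -> SvmConfig:
    """Pick the grid configuration maximizing mean stratified-CV balanced
    accuracy; ties resolve to the earliest grid entry."""
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    X = table.data.to_numpy(dtype=float)
    y = table.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_cfg, best_score = grid[0], -np.inf
    for cfg in grid:
        scores = []
        for tr, te in splits:
            sub = FeatureTable(table.data.iloc[tr].reset_index(drop=True), y[tr])
            m = train(sub, cfg)
            pred, _ = predict(m, X[te])
            tp = np.sum((pred == 1) & (y[te] == 1))
            tn = np.sum((pred == 0) & (y[te] == 0))
            npos = np.sum(y[te] == 1)
            nneg = np.sum(y[te] == 0)
            sens = tp / npos if npos else 0.0
            spec = tn / nneg if nneg else 0.0
            scores.append((sens + spec) / 2.0)
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_cfg = score, cfg
    return best_cfg
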