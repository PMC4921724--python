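"""Correlation-based feature selection (CFS).

A feature subset is worth keeping when its members correlate strongly with
the class label but weakly with one another. The merit of a k-feature
subset is the predicted correlation between the summed components and the
class:

    merit = k * mean|r_feature,class| / sqrt(k + k (k - 1) * mean|r_feature,feature|)

Forward best-first search over subsets, with a small patience, finds a
high-merit subset without enumerating all 2^p candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

__all__ = ["MeritState", "feature_class_correlation", "cfs_merit", "cfs_search"]


@dataclass
class MeritState:
    """A selected subset with its merit and the two average correlations
    that determine it."""

    subset: tuple[str, ...]
    merit: float
    r_zi_bar: float
    r_ii_bar: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def feature_class_correlation(table: FeatureTable, feature: str) -> float:
    """Absolute Pearson (point-biserial) correlation between one feature
    column and the 0/1 label; 0 (with a warning) for a constant feature."""
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    x = table.data[feature].to_numpy(dtype=float)
    if x.std() == 0:
        warnings.warn(f"feature {feature!r} is constant; correlation set to 0")
        return 0.0
    return abs(_pearson(x, labels.astype(float)))


def cfs_merit(k: int, r_zi_bar: float, r_ii_bar: float, sqrt: bool = True) -> float:
    """Composite-correlation merit of a k-feature subset.

    ``sqrt=False`` reproduces a variant without the square root over the
    denominator; the square-root form is the one consistent with the merit
    being a correlation of a summed composite.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    denom = k + k * (k - 1) * r_ii_bar
    if denom <= 0:
        raise ValueError("non-positive denominator: intercorrelations too negative")
    if sqrt:
        return k * r_zi_bar / np.sqrt(denom)
    return k * r_zi_bar / denom


def _merit_of(
    subset: list[str], rzc: dict[str, float], rff: "np.ndarray", pos: dict[str, int], sqrt: bool
) -> tuple[float, float, float]:
    k = len(subset)
    r_zi = float(np.mean([rzc[f] for f in subset]))
    if k == 1:
        r_ii = 0.0
    else:
        idx = [pos[f] for f in subset]
        sub = rff[np.ix_(idx, idx)]
        r_ii = float((sub.sum() - k) / (k * (k - 1)))
    return cfs_merit(k, r_zi, r_ii, sqrt=sqrt), r_zi, r_ii


def cfs_search(table: FeatureTable, patience: int = 5, sqrt: bool = True) -> MeritState:
    """Forward best-first search for the highest-merit subset.

    Starting from the empty set, the single feature addition maximizing
    merit is applied at every step (lexicographic tie-break on names);
    the search stops after ``patience`` consecutive expansions that fail to
    improve the best merit seen, which is then returned.
    """
    names = table.names
    if len(names) < 2:
        raise ValueError("need at least 2 features to search")
    X = table.data.to_numpy(dtype=float)
    y = table.labels.astype(float)
    rzc = {}
    for i, name in enumerate(names):
        col = X[:, i]
        rzc[name] = 0.0 if col.std() == 0 else abs(_pearson(col, y))
    # absolute feature-feature correlation matrix; constant columns -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cmat = np.corrcoef(X, rowvar=False)
    cmat = np.nan_to_num(np.abs(cmat), nan=0.0)
    np.fill_diagonal(cmat, 1.0)
    pos = {name: i for i, name in enumerate(names)}

    current: list[str] = []
    best_state: MeritState | None = None
    stale = 0
    while stale < patience and len(current) < len(names):
        candidates = sorted(set(names) - set(current))
        merit, cand, r_zi, r_ii = -np.inf, None, 0.0, 0.0
        for c in candidates:  # sorted order + strict > = lexicographic tie-break
            m, zi, ii = _merit_of(current + [c], rzc, cmat, pos, sqrt)
            if m > merit:
                merit, cand, r_zi, r_ii = m, c, zi, ii
        current.append(cand)
        state = MeritState(tuple(current), merit, r_zi, r_ii)
        if best_state is None or merit > best_state.merit:
            best_state = state
            stale = 0
        else:
            stale += 1
    assert best_state is not None
    return best_state
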