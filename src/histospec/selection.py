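"""Minimal-redundancy maximal-relevance (mRMR) feature ranking.

Relevance of a feature is its mutual information with the class label;
redundancy is its average mutual information with the already-selected set.
Ranking is greedy: the first feature maximizes I(feature, class), each next
feature maximizes

    I(feature, class) - (1/|S|) * sum_{s in S} I(feature, s),

the difference (MID) form of the criterion.  Mutual information is the
histogram plug-in estimate in bits; continuous features are discretized by
equal-frequency binning into min(10, ceil(sqrt(n))) bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankedFeatures", "mutual_information", "mrmr_rank", "discretize"]


@dataclass
class RankedFeatures:
    """Greedy mRMR selection path with per-step relevance and redundancy."""

    indices: list[int]
    relevance: list[float]   # I(selected, class) at each step
    redundancy: list[float]  # mean MI with the previously selected set
    names: list[str] | None = None

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.indices) + 1),
                "feature_index": self.indices,
                "feature_name": self.names if self.names is not None else self.indices,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
                "criterion": np.asarray(self.relevance) - np.asarray(self.redundancy),
            }
        )


def _n_bins(n: int) -> int:
    return min(10, int(np.ceil(np.sqrt(n))))


def discretize(x: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Integer codes for MI estimation.

    Variables with few distinct values (class labels, already-discrete
    features) are factorized as-is; continuous variables get equal-frequency
    bins.
    """
    x = np.asarray(x)
    n = x.size
    bins = n_bins if n_bins is not None else _n_bins(n)
    codes, uniques = pd.factorize(x, sort=True)
    if len(uniques) <= bins or not np.issubdtype(np.asarray(uniques).dtype, np.number):
        return codes.astype(np.int64)
    quantiles = np.quantile(x.astype(float), np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(quantiles), x.astype(float), side="left").astype(
        np.int64
    )


def _mi_codes(xc: np.ndarray, yc: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two integer-coded variables."""
    nx = int(xc.max()) + 1
    ny = int(yc.max()) + 1
    joint = np.bincount(xc * ny + yc, minlength=nx * ny).astype(float)
    joint = joint.reshape(nx, ny) / xc.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information I(x; y) in bits (symmetric, >= 0).

    Constant variables carry no information: MI = 0.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return _mi_codes(discretize(x), discretize(y))


def mrmr_rank(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    m: int,
) -> RankedFeatures:
    """Greedy mRMR ranking of ``m`` features; ties break toward lower index."""
    if m < 1:
        raise ValueError("m must be >= 1")
    names = None
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy()
    else:
        X = np.asarray(features)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if m > p:
        warnings.warn(f"m={m} exceeds {p} available features; truncating")
        m = p

    codes = np.empty((p, n), dtype=np.int64)
    for j in range(p):
        codes[j] = discretize(X[:, j])
    ycodes = discretize(np.asarray(labels).ravel())

    relevance = np.array([_mi_codes(codes[j], ycodes) for j in range(p)])
    selected: list[int] = []
    rel_path: list[float] = []
    red_path: list[float] = []
    red_sum = np.zeros(p)
    candidates = np.ones(p, dtype=bool)
    for step in range(m):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - red_sum / len(selected)
        score[~candidates] = -np.inf
        best = int(np.argmax(score))  # argmax returns the lowest tied index
        selected.append(best)
        rel_path.append(float(relevance[best]))
        red_path.append(float(red_sum[best] / len(selected[:-1])) if step else 0.0)
        candidates[best] = False
        if step < m - 1:
            for j in np.flatnonzero(candidates):
                red_sum[j] += _mi_codes(codes[j], codes[best])
    return RankedFeatures(
        indices=selected,
        relevance=rel_path,
        redundancy=red_path,
        names=[names[i] for i in selected] if names is not None else None,
    )
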