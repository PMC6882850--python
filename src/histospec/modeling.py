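"""Nested leave-one-subject-out cross-validation for neoplasia detection.

The outer loop holds one subject's images out for performance estimation;
the inner loop leaves one of the remaining subjects out to score every
(feature dimension m, SVM cost c, RBF width gamma) triple.  mRMR feature
ranking and z-scoring are fitted on inner-training data only, so no
information from a held-out subject leaks into selection or scaling.  The
best inner-mean-accuracy triple (ties broken toward smaller m, then c, then
gamma) is refit on the full outer-training set; pooled predictions give the
confusion matrix with neoplastic as the positive class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import GridConfig
from .selection import mrmr_rank

__all__ = ["CVReport", "nested_cv", "confusion_metrics"]

POSITIVE = "neoplastic"
NEGATIVE = "normal"


@dataclass
class FoldResult:
    held_out_subject: str
    m: int
    c: float
    gamma: float
    selected_features: list[str]
    image_ids: list[str]
    predictions: list[str]
    truths: list[str]


@dataclass
class CVReport:
    folds: list[FoldResult]
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    skipped_subjects: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion_metrics(
    predictions, labels, positive: str = POSITIVE
) -> tuple[dict, float, float, float]:
    """Confusion matrix and accuracy/sensitivity/specificity.

    Metrics whose denominator is empty (single-class ground truth) are
    reported as NaN-free 0.0 alongside a ``defined`` flag in the matrix
    dict rather than propagated as NaN.
    """
    predictions = list(predictions)
    labels = list(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    tp = sum(1 for p, t in zip(predictions, labels) if p == positive and t == positive)
    fn = sum(1 for p, t in zip(predictions, labels) if p != positive and t == positive)
    tn = sum(1 for p, t in zip(predictions, labels) if p != positive and t != positive)
    fp = sum(1 for p, t in zip(predictions, labels) if p == positive and t != positive)
    n = len(labels)
    matrix = {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity_defined": tp + fn > 0,
        "specificity_defined": tn + fp > 0,
    }
    accuracy = (tp + tn) / n if n else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return matrix, accuracy, sensitivity, specificity


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def _binary(labels: np.ndarray) -> np.ndarray:
    return np.asarray(
        [POSITIVE if lab == POSITIVE else NEGATIVE for lab in labels], dtype=object
    )


def nested_cv(
    features: pd.DataFrame,
    labels,
    subjects,
    grid: GridConfig | None = None,
    image_ids=None,
) -> CVReport:
    """Nested leave-one-subject-out CV with per-fold mRMR selection.

    ``features`` is images x named features; ``labels`` are 'normal' /
    'neoplastic'; ``subjects`` gives the subject id of each image.  Inner
    folds whose training half contains a single class are skipped with a
    warning; zero-variance features are dropped per training fold before
    ranking.
    """
    grid = grid or GridConfig()
    X_all = features.to_numpy(dtype=float)
    names = list(features.columns)
    y_all = _binary(np.asarray(labels))
    subj = np.asarray(subjects)
    ids = (
        np.asarray(image_ids)
        if image_ids is not None
        else np.asarray([f"img{i}" for i in range(len(y_all))])
    )
    unique_subjects = list(dict.fromkeys(subj.tolist()))
    if len(unique_subjects) < 2:
        raise ValueError("nested CV needs at least 2 subjects")
    if len(set(y_all)) < 2:
        raise ValueError("both classes must be present overall")

    folds: list[FoldResult] = []
    skipped: list[str] = []
    for held_out in unique_subjects:
        outer_test = subj == held_out
        outer_train = ~outer_test
        inner_subjects = [s for s in unique_subjects if s != held_out]

        scores: dict[tuple[int, float, float], list[float]] = {}
        for inner_val in inner_subjects:
            val_mask = subj == inner_val
            tr_mask = outer_train & ~val_mask
            y_tr = y_all[tr_mask]
            if len(set(y_tr)) < 2:
                warnings.warn(
                    f"inner fold {inner_val} under {held_out}: single-class "
                    "training set, skipped"
                )
                continue
            X_tr, X_val = X_all[tr_mask], X_all[val_mask]
            keep = X_tr.std(axis=0) > 0
            mu, sd = _fit_scaler(X_tr[:, keep])
            Z_tr = (X_tr[:, keep] - mu) / sd
            Z_val = (X_val[:, keep] - mu) / sd
            m_max = min(max(grid.m_grid), Z_tr.shape[1])
            ranking = mrmr_rank(Z_tr, y_tr, m_max)
            order = np.asarray(ranking.indices)
            for m in grid.m_grid:
                m_eff = min(m, len(order))
                cols = order[:m_eff]
                for c in grid.c_grid:
                    for g in grid.gamma_grid:
                        clf = SVC(C=c, gamma=g, kernel="rbf")
                        clf.fit(Z_tr[:, cols], y_tr)
                        acc = float(np.mean(clf.predict(Z_val[:, cols]) == y_all[val_mask]))
                        scores.setdefault((m, c, g), []).append(acc)
        if not scores:
            skipped.append(held_out)
            continue
        # best mean inner accuracy; ties toward smaller m, then c, then gamma
        best_key = max(
            sorted(scores),
            key=lambda k: (np.mean(scores[k]), -k[0], -k[1], -k[2]),
        )
        m_best, c_best, g_best = best_key

        X_tr, X_te = X_all[outer_train], X_all[outer_test]
        y_tr = y_all[outer_train]
        keep = X_tr.std(axis=0) > 0
        kept_names = [n for n, k in zip(names, keep) if k]
        mu, sd = _fit_scaler(X_tr[:, keep])
        Z_tr = (X_tr[:, keep] - mu) / sd
        Z_te = (X_te[:, keep] - mu) / sd
        m_eff = min(m_best, Z_tr.shape[1])
        ranking = mrmr_rank(Z_tr, y_tr, m_eff)
        cols = np.asarray(ranking.indices)
        clf = SVC(C=c_best, gamma=g_best, kernel="rbf")
        clf.fit(Z_tr[:, cols], y_tr)
        preds = clf.predict(Z_te[:, cols])

        # leakage guard: no held-out image may appear in the training fold
        assert not set(ids[outer_test]) & set(ids[outer_train])
        folds.append(
            FoldResult(
                held_out_subject=str(held_out),
                m=int(m_best),
                c=float(c_best),
                gamma=float(g_best),
                selected_features=[kept_names[i] for i in cols],
                image_ids=ids[outer_test].tolist(),
                predictions=preds.tolist(),
                truths=y_all[outer_test].tolist(),
            )
        )

    all_preds = [p for f in folds for p in f.predictions]
    all_truth = [t for f in folds for t in f.truths]
    matrix, acc, sens, spec = confusion_metrics(all_preds, all_truth)
    return CVReport(
        folds=folds,
        tp=matrix["tp"],
        fp=matrix["fp"],
        tn=matrix["tn"],
        fn=matrix["fn"],
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        skipped_subjects=skipped,
    )
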