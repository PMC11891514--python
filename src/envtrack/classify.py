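"""Individual-level aphasia detection from per-band multivariate TMIFs.

Features are the multivariate TMIFs of the five narrow bands (lag axis
pruned from 0 ms up to a tuned length) plus age.  The classifier is an
RBF-kernel SVM evaluated with nested cross-validation: leave-one-subject-
out on the outside, stratified 5-fold accuracy-based selection of the C
hyperparameter and the TMIF pruning length on the inside.  Standardization
parameters are learned on training subjects only.  Feature contributions
are Shapley values over feature groups (one group per band, plus age),
computed exactly by enumerating group coalitions against a training-data
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import FEATURE_BANDS
from .mi import TMIF

POSITIVE_CLASS = "aphasia"
C_GRID: tuple[float, ...] = tuple(np.logspace(-2, 2, 9))
PRUNE_GRID_MS: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass
class FeatureMatrix:
    """Subjects x (band TMIF lags ... + age)."""

    X: np.ndarray
    columns: list[tuple[str, float | None]]  # (band, lag_ms) or ("age", None)
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.subject_ids), len(self.columns)):
            raise ValueError("feature matrix shape mismatch")
        if np.isnan(self.X).any():
            raise ValueError("missing values in features")

    def prune_mask(self, prune_ms: float) -> np.ndarray:
        """Columns kept at a given pruning length: per-band lags in
        [0, prune_ms]; age is always kept."""
        return np.array([
            band == "age" or (lag is not None and 0.0 <= lag <= prune_ms)
            for band, lag in self.columns
        ])

    def group_indices(self) -> dict[str, np.ndarray]:
        names = [band for band, _ in self.columns]
        return {g: np.nonzero([n == g for n in names])[0]
                for g in dict.fromkeys(names)}


def build_features(
    band_tmifs: dict[str, list[TMIF]],
    ages: list[float],
    subject_ids: list[str] | None = None,
    bands: tuple[str, ...] = FEATURE_BANDS,
) -> FeatureMatrix:
    """Concatenate per-band multivariate TMIFs (nonnegative lags) + age."""
    n = len(ages)
    subject_ids = subject_ids or [f"sub-{i + 1:03d}" for i in range(n)]
    blocks, columns = [], []
    for band in bands:
        tmifs = band_tmifs[band]
        if len(tmifs) != n:
            raise ValueError(f"band {band!r}: {len(tmifs)} TMIFs for {n} subjects")
        lags = tmifs[0].lags_ms
        for t in tmifs[1:]:
            if not np.array_equal(t.lags_ms, lags):
                raise ValueError("inconsistent lag grids across subjects")
        keep = lags >= 0.0
        blocks.append(np.stack([t.channel_average()[keep] for t in tmifs]))
        columns.extend((band, float(l)) for l in lags[keep])
    blocks.append(np.asarray(ages, dtype=float)[:, None])
    columns.append(("age", None))
    return FeatureMatrix(np.concatenate(blocks, axis=1), columns, list(subject_ids))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    accuracy: float
    f1: float
    auc: float
    sensitivity: float
    specificity: float
    roc: list[tuple[float, float]]
    predictions: list[dict] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "roc": self.roc, "predictions": self.predictions,
            "chosen_params": self.chosen_params,
        }


def metrics(y_true: np.ndarray, y_pred: np.ndarray,
            decision_values: np.ndarray) -> ClassifierReport:
    """Performance metrics with aphasia as the positive class.

    ``y_true``/``y_pred`` are 0/1 with 1 = aphasia; decision values are
    signed distances (positive toward aphasia).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or len(np.unique(y_true)) < 1:
        raise ValueError("empty input")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("metrics undefined with a single-class ground truth")
    accuracy = (tp + tn) / y_true.size
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    f1 = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0.0))
    decision_values = np.asarray(decision_values, dtype=float)
    auc = float(roc_auc_score(y_true, decision_values))
    fpr, tpr, _ = roc_curve(y_true, decision_values)
    return ClassifierReport(
        accuracy=float(accuracy), f1=f1, auc=auc,
        sensitivity=float(sensitivity), specificity=float(specificity),
        roc=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _fit_svm(Xtr: np.ndarray, ytr: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="rbf", C=C, gamma="scale", class_weight="balanced")
    clf.fit(Xtr, ytr)
    return clf


def _inner_accuracy(X: np.ndarray, y: np.ndarray, mask: np.ndarray, C: float,
                    rng_seed: int, n_splits: int = 5) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
    correct = total = 0
    for tr, va in skf.split(X, y):
        Xtr, Xva = _standardize(X[np.ix_(tr, np.nonzero(mask)[0])],
                                X[np.ix_(va, np.nonzero(mask)[0])])
        clf = _fit_svm(Xtr, y[tr], C)
        correct += int(np.sum(clf.predict(Xva) == y[va]))
        total += va.size
    return correct / total


def nested_cv_svm(
    features: FeatureMatrix,
    labels: list[str] | np.ndarray,
    seed: int = 0,
    c_grid: tuple[float, ...] = C_GRID,
    prune_grid_ms: tuple[float, ...] = PRUNE_GRID_MS,
    inner_splits: int = 5,
) -> ClassifierReport:
    """Leave-one-subject-out SVM with inner 5-fold selection of (C, prune).

    The inner grid is scanned jointly; ties keep the first (shortest prune,
    smallest C) combination, making the whole procedure deterministic given
    the seed.
    """
    y = np.array([1 if lab == POSITIVE_CLASS else 0 for lab in labels], dtype=int)
    if min(np.sum(y == 1), np.sum(y == 0)) < inner_splits + 1:
        raise ValueError(f"need at least {inner_splits + 1} subjects per class")
    n = y.size
    X = features.X
    masks = {p: features.prune_mask(p) for p in prune_grid_ms}
    y_pred = np.empty(n, dtype=int)
    decision = np.empty(n, dtype=float)
    chosen = []
    for held_out in range(n):
        tr = np.delete(np.arange(n), held_out)
        if len(np.unique(y[tr])) < 2:
            raise ValueError("class absent from a training fold")
        best = (-np.inf, None, None)
        for prune in prune_grid_ms:
            for C in c_grid:
                acc = _inner_accuracy(X[tr], y[tr], masks[prune], C,
                                      rng_seed=seed + held_out, n_splits=inner_splits)
                if acc > best[0]:
                    best = (acc, prune, C)
        _, prune, C = best
        cols = np.nonzero(masks[prune])[0]
        Xtr, Xte = _standardize(X[np.ix_(tr, cols)], X[np.ix_([held_out], cols)])
        clf = _fit_svm(Xtr, y[tr], C)
        y_pred[held_out] = int(clf.predict(Xte)[0])
        raw = float(clf.decision_function(Xte)[0])
        # SVC orients decision_function toward classes_[1]; flip if needed
        decision[held_out] = raw if clf.classes_[1] == 1 else -raw
        chosen.append({"held_out": features.subject_ids[held_out],
                       "C": float(C), "prune_ms": float(prune),
                       "inner_accuracy": float(best[0])})
    report = metrics(y, y_pred, decision)
    report.predictions = [
        {"subject_id": sid, "true": int(t), "predicted": int(p), "decision": float(d)}
        for sid, t, p, d in zip(features.subject_ids, y, y_pred, decision)
    ]
    report.chosen_params = chosen
    return report


# ---------------------------------------------------------------------------
# Shapley feature attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionReport:
    group_names: list[str]
    values: np.ndarray  # subjects x groups, signed toward the aphasia class
    baseline: float
    decisions: np.ndarray

    def ranking(self) -> list[str]:
        order = np.argsort(-np.abs(self.values).mean(axis=0), kind="stable")
        return [self.group_names[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.group_names)
        df.insert(0, "decision", self.decisions)
        return df


def shapley_attribution(
    decision_fn,
    X: np.ndarray,
    feature_groups: dict[str, np.ndarray],
    background: np.ndarray,
    max_exact_groups: int = 14,
    n_mc: int = 2000,
    seed: int | None = None,
) -> AttributionReport:
    """Group-level Shapley values of a decision function.

    The coalition value is the mean decision over background rows with the
    out-of-coalition feature groups replaced by background values.  With
    few groups (the band + age grouping has six) the Shapley sum is
    enumerated exactly, so additivity holds to numerical precision; larger
    groupings fall back to Monte-Carlo permutation sampling.
    """
    background = np.atleast_2d(background)
    if background.shape[0] == 0:
        raise ValueError("background must contain at least one row")
    X = np.atleast_2d(X)
    names = list(feature_groups)
    g = len(names)
    n, b = X.shape[0], background.shape[0]

    def coalition_values(subsets: list[tuple[int, ...]]) -> dict[tuple[int, ...], np.ndarray]:
        out = {}
        for S in subsets:
            cols = np.concatenate([feature_groups[names[i]] for i in S]) if S else np.array([], dtype=int)
            Z = np.repeat(background[None, :, :], n, axis=0)  # n x b x p
            if cols.size:
                Z[:, :, cols] = X[:, None, cols]
            vals = decision_fn(Z.reshape(n * b, -1)).reshape(n, b).mean(axis=1)
            out[S] = vals
        return out

    if g <= max_exact_groups:
        subsets = [tuple(sorted(S)) for k in range(g + 1) for S in combinations(range(g), k)]
        v = coalition_values(subsets)
        phi = np.zeros((n, g))
        for i in range(g):
            for S in subsets:
                if i in S:
                    continue
                w = 1.0 / ((g) * comb(g - 1, len(S)))
                phi[:, i] += w * (v[tuple(sorted(S + (i,)))] - v[S])
        baseline = float(v[()].mean())
        decisions = v[tuple(range(g))]
    else:  # Monte-Carlo permutation estimator
        rng = np.random.default_rng(seed)
        phi = np.zeros((n, g))
        empty = coalition_values([()])[()]
        full = coalition_values([tuple(range(g))])[tuple(range(g))]
        for _ in range(n_mc):
            perm = rng.permutation(g)
            prev = empty
            S: tuple[int, ...] = ()
            for i in perm:
                S = tuple(sorted(S + (int(i),)))
                cur = coalition_values([S])[S]
                phi[:, i] += cur - prev
                prev = cur
        phi /= n_mc
        baseline = float(empty.mean())
        decisions = full
    return AttributionReport(names, phi, baseline, decisions)
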