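"""Cross-validated classification of patients vs controls.

Two feature-selection protocols are first-class:

``nested``
    the edge-wise t-test selection is re-run inside every training fold, so
    the test fold never influences which edges become features (unbiased).
``pooled``
    edges are selected once on the full cohort before cross-validation.
    This replicates a protocol common in the connectivity-classification
    literature, and on null data it inflates accuracy above chance because
    the held-out subjects leak into the selection step.

Metrics are micro-averaged: confusion counts are pooled over folds before
computing accuracy, sensitivity (patients correctly classified) and
specificity (controls correctly classified); with only a handful of
subjects per fold, per-fold rates are too unstable to average.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .group_stats import edge_ttests, select_edges
from .svm import predict, train_svm

PATIENT, CONTROL = 1, -1


@dataclass
class FoldPlan:
    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train indices, test indices)
    seed: int


def make_folds(labels: np.ndarray, k: int = 10, seed: int = 0,
               stratified: bool = True) -> FoldPlan:
    """Deterministic (stratified) k-fold partition.

    Fold sizes differ by at most 1 and, when stratified, each fold's class
    counts are within +-1 of proportional.  Subjects are shuffled within
    class by a generator seeded with ``seed``, then dealt to folds.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    if k < 2:
        raise ValueError("need k >= 2")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    classes = [labels == u for u in np.unique(labels)] if stratified \
        else [np.ones(n, dtype=bool)]
    extra_start = 0
    for mask in classes:
        idx = rng.permutation(np.flatnonzero(mask))
        n_c = idx.size
        base, extra = divmod(n_c, k)
        counts = np.full(k, base)
        # rotate where the oversized folds start so totals stay balanced
        counts[[(extra_start + i) % k for i in range(extra)]] += 1
        extra_start += extra
        pos = 0
        for f in range(k):
            assignment[idx[pos:pos + counts[f]]] = f
            pos += counts[f]
    folds = []
    for f in range(k):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        folds.append((train, test))
    return FoldPlan(k=k, folds=folds, seed=seed)


@dataclass
class FoldResult:
    fold: int
    tp: int
    tn: int
    fp: int
    fn: int
    n_selected: int
    skipped: bool = False
    warning: str | None = None


@dataclass
class ClassificationReport:
    folds: list[FoldResult]
    selection_mode: str
    threshold: float
    C: float
    k: int
    seed: int
    tp: int = field(init=False)
    tn: int = field(init=False)
    fp: int = field(init=False)
    fn: int = field(init=False)

    def __post_init__(self):
        self.tp = sum(f.tp for f in self.folds)
        self.tn = sum(f.tn for f in self.folds)
        self.fp = sum(f.fp for f in self.folds)
        self.fn = sum(f.fn for f in self.folds)

    @property
    def n_tested(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        n = self.n_tested
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def n_skipped_folds(self) -> int:
        return sum(1 for f in self.folds if f.skipped)

    def to_dict(self) -> dict:
        return {
            "selection_mode": self.selection_mode,
            "threshold": self.threshold,
            "C": self.C,
            "k": self.k,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": self.tp, "tn": self.tn,
                          "fp": self.fp, "fn": self.fn},
            "n_tested": self.n_tested,
            "per_fold": [
                {"fold": f.fold, "tp": f.tp, "tn": f.tn, "fp": f.fp,
                 "fn": f.fn, "n_selected": f.n_selected,
                 "skipped": f.skipped, "warning": f.warning}
                for f in self.folds
            ],
        }


def cross_validate(edge_table: np.ndarray, labels: np.ndarray, k: int = 10,
                   selection_mode: str = "nested", threshold: float = 0.001,
                   C: float = 1.0, seed: int = 0, welch: bool = False,
                   stratified: bool = True) -> ClassificationReport:
    """k-fold cross-validated linear-SVM classification on edge features.

    ``edge_table`` is subjects x edges; ``labels`` uses +1 for patients and
    -1 for controls.  In nested mode a training fold in which no edge
    passes selection is skipped with a warning and reported as such.
    """
    if selection_mode not in ("nested", "pooled"):
        raise ValueError("selection_mode must be 'nested' or 'pooled'")
    X = np.asarray(edge_table, dtype=float)
    y = np.asarray(labels, dtype=int)
    plan = make_folds(y, k=k, seed=seed, stratified=stratified)

    pooled_selected: list[int] | None = None
    if selection_mode == "pooled":
        stats = edge_ttests(X[y == PATIENT], X[y == CONTROL], welch=welch)
        pooled_selected = select_edges(stats, threshold).selected

    results = []
    for f, (train, test) in enumerate(plan.folds):
        if np.unique(y[train]).size < 2:
            results.append(FoldResult(f, 0, 0, 0, 0, 0, skipped=True,
                                      warning="single-class training fold"))
            continue
        if selection_mode == "nested":
            stats = edge_ttests(X[train][y[train] == PATIENT],
                                X[train][y[train] == CONTROL], welch=welch)
            selected = select_edges(stats, threshold).selected
        else:
            selected = pooled_selected
        if not selected:
            results.append(FoldResult(f, 0, 0, 0, 0, 0, skipped=True,
                                      warning="no edges survived selection"))
            continue
        model = train_svm(X[np.ix_(train, selected)], y[train].astype(float),
                          C=C)
        pred = predict(model, X[np.ix_(test, selected)])
        truth = y[test]
        results.append(FoldResult(
            fold=f,
            tp=int(np.sum((pred == PATIENT) & (truth == PATIENT))),
            tn=int(np.sum((pred == CONTROL) & (truth == CONTROL))),
            fp=int(np.sum((pred == PATIENT) & (truth == CONTROL))),
            fn=int(np.sum((pred == CONTROL) & (truth == PATIENT))),
            n_selected=len(selected),
        ))
    return ClassificationReport(folds=results, selection_mode=selection_mode,
                                threshold=threshold, C=C, k=k, seed=seed)
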