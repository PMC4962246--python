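"""Confusion-table metrics and repeated k-fold cross-validation.

Five statistics summarise a binary ER-binder confusion table: accuracy,
sensitivity, specificity, the Matthews correlation coefficient (MCC) and
balanced accuracy.  Model stability is estimated by repeated five-fold
cross-validation: each repetition draws a fresh random partition, fits a
Decision Forest on four folds and predicts the held-out fold, so that
every compound is tested exactly once per repetition; the five held-out
prediction sets are pooled into a single confusion table per repetition
and the repetition-level metrics are averaged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from erscreen.dataset_io import LabeledDataset
from erscreen.decision_forest import (
    DecisionForest,
    TreeParams,
    classify,
    fit_forest,
    predict_proba,
)

__all__ = [
    "ConfusionTable",
    "MetricsSummary",
    "CVResult",
    "confusion",
    "metrics",
    "kfold_split",
    "cross_validate",
    "external_validate",
    "cv_result_to_frame",
    "cv_result_to_json",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc", "balanced_accuracy")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of binder/non-binder calls against truth.

    TP = binders called binders, TN = non-binders called non-binders,
    FP = non-binders called binders, FN = binders called non-binders.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsSummary:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    balanced_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class CVResult:
    """Repeated k-fold cross-validation summary.

    ``per_iteration`` holds one :class:`MetricsSummary` per repetition
    (pooled over the k held-out folds); ``mean`` and ``std`` are computed
    across repetitions (population std, ddof=0).
    """

    per_iteration: list[MetricsSummary]
    k: int
    repeats: int
    seed: int

    @property
    def mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([getattr(m, name) for m in self.per_iteration]))
            for name in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            name: float(np.std([getattr(m, name) for m in self.per_iteration]))
            for name in METRIC_NAMES
        }


def confusion(truth, calls) -> ConfusionTable:
    """Tally the 2x2 confusion table from aligned 0/1 vectors."""
    t = np.asarray(truth, dtype=np.int64)
    c = np.asarray(calls, dtype=np.int64)
    if t.shape != c.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs calls {c.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(c, (0, 1)).all()):
        raise ValueError("truth and calls must be binary 0/1")
    return ConfusionTable(
        tp=int(np.sum((t == 1) & (c == 1))),
        tn=int(np.sum((t == 0) & (c == 0))),
        fp=int(np.sum((t == 0) & (c == 1))),
        fn=int(np.sum((t == 1) & (c == 0))),
    )


def metrics(ct: ConfusionTable) -> MetricsSummary:
    """Evaluate the five performance statistics of a confusion table.

    MCC with any zero denominator factor is defined as 0 (the standard
    convention for a degenerate margin).  Sensitivity requires at least
    one true binder and specificity at least one true non-binder.
    """
    tp, tn, fp, fn = ct.tp, ct.tn, ct.fp, ct.fn
    n = ct.total
    if n == 0:
        raise ValueError("empty confusion table")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError(
            "sensitivity/specificity undefined: one class absent from truth"
        )
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    balanced = (tp * (tn + fp) + tn * (tp + fn)) / (2 * (tp + fn) * (tn + fp))
    return MetricsSummary(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=mcc,
        balanced_accuracy=balanced,
    )


def kfold_split(
    n: int, k: int, seed: int, labels: np.ndarray | None = None, stratified: bool = False
) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into k folds of near-equal size.

    Folds are disjoint, cover all indices and differ in size by at most
    one.  Plain random by default; ``stratified=True`` balances the class
    ratio across folds (requires *labels*).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    if stratified:
        if labels is None:
            raise ValueError("stratified splitting requires labels")
        folds: list[list[int]] = [[] for _ in range(k)]
        slot = 0
        for cls in (1, 0):
            idx = np.flatnonzero(np.asarray(labels) == cls)
            idx = rng.permutation(idx)
            for i in idx:
                folds[slot % k].append(int(i))
                slot += 1
        return [np.sort(np.array(f, dtype=np.int64)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _run_one_repetition(
    ds: LabeledDataset,
    params: TreeParams,
    k: int,
    seed: int,
    stratified: bool,
    max_retries: int = 10,
) -> ConfusionTable:
    """One k-fold pass: pooled held-out confusion table.

    If a random partition leaves a training split with only one class the
    partition is redrawn with an offset seed, up to *max_retries* times.
    """
    y = ds.label_array()
    n = ds.n_compounds
    for attempt in range(max_retries + 1):
        folds = kfold_split(n, k, seed + attempt * 104729, labels=y, stratified=stratified)
        ok = True
        for fold in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[fold] = False
            if len(np.unique(y[train_mask])) < 2:
                ok = False
                break
        if ok:
            if attempt:
                logger.info("repartitioned %d time(s) to keep both classes", attempt)
            break
    else:
        raise RuntimeError(
            f"could not draw a {k}-fold partition keeping both classes "
            f"in every training split after {max_retries} retries"
        )

    truth_all: list[np.ndarray] = []
    calls_all: list[np.ndarray] = []
    for fold in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[fold] = False
        train = ds.subset_rows(np.flatnonzero(train_mask))
        test = ds.subset_rows(fold)
        forest = fit_forest(train, params)
        p = predict_proba(forest, test)
        truth_all.append(y[fold])
        calls_all.append(np.asarray(classify(p)))
    return confusion(np.concatenate(truth_all), np.concatenate(calls_all))


def cross_validate(
    ds: LabeledDataset,
    params: TreeParams = TreeParams(),
    k: int = 5,
    repeats: int = 200,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of a Decision Forest on *ds*.

    Each repetition uses an independent random partition (derived from
    *seed*), fits a fresh forest per fold and pools the k held-out
    prediction sets into one confusion table, so every compound is tested
    once and only once per repetition.
    """
    if not ds.is_labeled():
        raise ValueError("cross_validate requires a labeled dataset")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    y = ds.label_array()
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    per_iteration = []
    for rep in range(repeats):
        ct = _run_one_repetition(ds, params, k, seed + rep * 1000003, stratified)
        per_iteration.append(metrics(ct))
    return CVResult(per_iteration=per_iteration, k=k, repeats=repeats, seed=seed)


def external_validate(forest: DecisionForest, external: LabeledDataset) -> MetricsSummary:
    """Score an already-fitted forest on an independent labeled set (no refit)."""
    if not external.is_labeled():
        raise ValueError("external validation requires labels")
    p = predict_proba(forest, external)
    ct = confusion(external.label_array(), np.asarray(classify(p)))
    return metrics(ct)


def cv_result_to_frame(result: CVResult) -> pd.DataFrame:
    """Long-format table (repetition, metric, value) — boxplot-ready."""
    rows = [
        {"repetition": i, "metric": name, "value": getattr(m, name)}
        for i, m in enumerate(result.per_iteration)
        for name in METRIC_NAMES
    ]
    return pd.DataFrame(rows, columns=["repetition", "metric", "value"])


def cv_result_to_json(result: CVResult, params: TreeParams | None = None) -> str:
    doc = {
        "k": result.k,
        "repeats": result.repeats,
        "seed": result.seed,
        "mean": result.mean,
        "std": result.std,
    }
    if params is not None:
        doc["hyperparams"] = {
            "max_depth": params.max_depth,
            "min_leaf_size": params.min_leaf_size,
            "min_split_size": params.min_split_size,
            "impurity": params.impurity,
            "max_trees": params.max_trees,
        }
    return json.dumps(doc, indent=1)
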