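"""Outcome-based evaluation of patient similarity matrices.

Two evaluation modes:

* **pairwise** — every unordered patient pair is predicted "similar" or not
  by a cutoff rule on the similarity matrix (global threshold, per-patient
  top-K, or top-p% of the cohort) and scored against label equality,
  yielding TP/TN/FP/FN where a true positive is a pair predicted similar
  whose outcomes agree.
* **patient_knn** — each held-out patient receives the majority outcome of
  its K most-similar training patients (K optionally derived from a
  percentage p of the training fold), scored as ordinary classification
  under stratified k-fold cross-validation.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import SimilarityMatrix


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float
    recall: float
    precision: float
    f1: float
    zero_division: bool = False


@dataclass
class CutoffRule:
    """One active rule deciding which pairs count as predicted-similar."""

    kind: Literal["threshold", "top_k", "top_p"]
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "top_k", "top_p"):
            raise ValueError(f"unknown cutoff rule {self.kind!r}")


@dataclass
class EvalProtocol:
    mode: Literal["pairwise", "patient_knn"] = "patient_knn"
    cutoff: CutoffRule = field(default_factory=lambda: CutoffRule("top_k", 5))
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, recall, precision and F1 from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); recall = TP/(TP+FN);
    precision = TP/(TP+FP); F1 = 2*recall*precision/(recall+precision).
    Division by zero in recall/precision/F1 yields 0 with the
    ``zero_division`` flag set.
    """
    if c.total <= 0:
        raise ValueError("no evaluated pairs")
    acc = (c.tp + c.tn) / c.total
    flag = False
    if c.tp + c.fn > 0:
        rec = c.tp / (c.tp + c.fn)
    else:
        rec, flag = 0.0, True
    if c.tp + c.fp > 0:
        prec = c.tp / (c.tp + c.fp)
    else:
        prec, flag = 0.0, True
    if rec + prec > 0:
        f1 = 2.0 * rec * prec / (rec + prec)
    else:
        f1, flag = 0.0, True
    return Metrics(acc, rec, prec, f1, flag)


def _predicted_similar(m: SimilarityMatrix, rule: CutoffRule) -> np.ndarray:
    """Boolean (n, n) matrix of predicted-similar pairs (symmetric, zero diag)."""
    n = m.n
    vals = m.values
    if rule.kind == "threshold":
        pred = vals >= rule.value
    else:
        if rule.kind == "top_p":
            k = max(1, math.ceil(rule.value / 100.0 * (n - 1)))
        else:
            k = int(rule.value)
        k = min(k, n - 1)
        ranked = vals.copy()
        np.fill_diagonal(ranked, -np.inf)
        order = np.argsort(-ranked, axis=1, kind="stable")[:, :k]
        pred = np.zeros((n, n), dtype=bool)
        pred[np.repeat(np.arange(n), k), order.ravel()] = True
        pred = pred | pred.T  # a pair is similar if either patient lists the other
    out = np.asarray(pred, dtype=bool).copy()
    np.fill_diagonal(out, False)
    return out


def pairwise_confusion(
    m: SimilarityMatrix, outcomes: Sequence, rule: CutoffRule
) -> ConfusionCounts:
    """Score all unordered pairs: predicted-similar vs outcome equality."""
    labels = np.asarray(outcomes, dtype=object)
    if len(labels) != m.n:
        raise ValueError("outcomes must match matrix size")
    if len(set(labels.tolist())) < 2:
        warnings.warn("single outcome class: TN/FP are structurally zero")
    pred = _predicted_similar(m, rule)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(m.n, k=1)
    p, s = pred[iu], same[iu]
    return ConfusionCounts(
        tp=int(np.sum(p & s)),
        tn=int(np.sum(~p & ~s)),
        fp=int(np.sum(p & ~s)),
        fn=int(np.sum(~p & s)),
    )


def resolve_k(k: int | None, p_percent: float | None, n_train: int) -> int:
    """Neighbor count from an explicit K or a percentage of the training fold."""
    if (k is None) == (p_percent is None):
        raise ValueError("specify exactly one of k or p_percent")
    if p_percent is not None:
        k = math.ceil(p_percent / 100.0 * n_train)
    k = max(1, int(k))
    if k > n_train:
        raise ValueError(f"K={k} exceeds training-fold size {n_train}")
    return k


def patient_knn_predict(
    m: SimilarityMatrix,
    outcomes: Sequence,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    k: int | None = None,
    p_percent: float | None = None,
) -> np.ndarray:
    """Predict each test patient's outcome by majority vote of its K most
    similar training patients.

    Vote ties break to the most frequent class in the training fold, then to
    the lower class in sorted label order.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if train_idx.size == 0:
        raise ValueError("empty training fold")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test folds overlap")
    labels = np.asarray(outcomes, dtype=object)
    kk = resolve_k(k, p_percent, train_idx.size)

    train_labels = labels[train_idx]
    fold_freq = Counter(train_labels.tolist())
    label_rank = {lab: i for i, lab in enumerate(sorted(set(labels.tolist()), key=str))}

    sims = m.values[np.ix_(test_idx, train_idx)]
    # stable descending sort: equal similarities keep lower train position first
    order = np.argsort(-sims, axis=1, kind="stable")[:, :kk]
    preds = np.empty(test_idx.size, dtype=object)
    for row, neigh in enumerate(order):
        votes = Counter(train_labels[neigh].tolist())
        best = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == best]
        tied.sort(key=lambda lab: (-fold_freq[lab], label_rank[lab]))
        preds[row] = tied[0]
    return preds


def crossvalidate(
    m: SimilarityMatrix,
    outcomes: Sequence,
    protocol: EvalProtocol,
    k: int | None = None,
    p_percent: float | None = None,
) -> pd.DataFrame:
    """Stratified k-fold evaluation of a similarity matrix.

    In ``patient_knn`` mode each fold's held-out patients are classified by
    :func:`patient_knn_predict` and scored patient-level (a correct patient
    counts as TP if its class matches, against a one-vs-rest reading for
    precision/recall via micro-averaged pair terms: here accuracy is the
    primary figure and recall/precision/F1 are macro-averaged across
    classes). In ``pairwise`` mode the cutoff rule is applied within each
    held-out fold's submatrix. Returns a tidy frame (fold, metric, value)
    including ``mean``/``std`` summary rows; deterministic under the seed.
    """
    labels = np.asarray(outcomes, dtype=object)
    n = m.n
    if n < protocol.folds:
        raise ValueError("fewer patients than folds")
    counts = Counter(labels.tolist())
    if min(counts.values()) < protocol.folds:
        warnings.warn("a class has fewer members than folds; falling back to unstratified splits")
        splitter = KFold(n_splits=protocol.folds, shuffle=True, random_state=protocol.seed)
        split_iter = splitter.split(np.arange(n))
    else:
        splitter = StratifiedKFold(n_splits=protocol.folds, shuffle=True, random_state=protocol.seed)
        split_iter = splitter.split(np.arange(n), labels.astype(str))

    rows = []
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        if protocol.mode == "patient_knn":
            preds = patient_knn_predict(m, labels, train_idx, test_idx, k=k, p_percent=p_percent)
            truth = labels[test_idx]
            acc = float(np.mean(preds == truth))
            rec, prec, f1 = _macro_prf(truth, preds)
        else:
            sub = SimilarityMatrix(
                m.values[np.ix_(test_idx, test_idx)],
                [m.patient_ids[i] for i in test_idx],
                m.kind,
            )
            mm = metrics(pairwise_confusion(sub, labels[test_idx], protocol.cutoff))
            acc, rec, prec, f1 = mm.accuracy, mm.recall, mm.precision, mm.f1
        rows.append({"fold": fold, "accuracy": acc, "recall": rec, "precision": prec, "f1": f1})

    per_fold = pd.DataFrame(rows)
    tidy = per_fold.melt(id_vars="fold", var_name="metric", value_name="value")
    summary = []
    for metric_name in ("accuracy", "recall", "precision", "f1"):
        vals = per_fold[metric_name]
        summary.append({"fold": "mean", "metric": metric_name, "value": float(vals.mean())})
        summary.append({"fold": "std", "metric": metric_name, "value": float(vals.std(ddof=0))})
    return pd.concat([tidy, pd.DataFrame(summary)], ignore_index=True)


def _macro_prf(truth: np.ndarray, preds: np.ndarray) -> tuple[float, float, float]:
    classes = sorted(set(truth.tolist()) | set(preds.tolist()), key=str)
    recs, precs, f1s = [], [], []
    for c in classes:
        tp = int(np.sum((preds == c) & (truth == c)))
        fp = int(np.sum((preds == c) & (truth != c)))
        fn = int(np.sum((preds != c) & (truth == c)))
        rec = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * rec * prec / (rec + prec) if rec + prec else 0.0
        recs.append(rec)
        precs.append(prec)
        f1s.append(f1)
    return float(np.mean(recs)), float(np.mean(precs)), float(np.mean(f1s))


def cv_summary(result: pd.DataFrame, metric: str = "accuracy") -> tuple[float, float]:
    """(mean, std) of a metric from a crossvalidate result frame."""
    mean = float(result.query("fold == 'mean' and metric == @metric")["value"].iloc[0])
    std = float(result.query("fold == 'std' and metric == @metric")["value"].iloc[0])
    return mean, std
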