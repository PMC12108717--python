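"""Cross-validation harness and ranking metrics.

Known associations are split into folds; each fold is hidden from the
training matrix in turn, the model is refit, and the held-out positives
are ranked against every unknown cell.  Reported metrics: AUC, AUPR and
the confusion-matrix family (accuracy, sensitivity/recall, specificity,
precision, F1) at a per-fold threshold.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import model
from .containers import (
    AssociationMatrix,
    Hyperparameters,
    SimilarityMatrix,
)
from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "CVFoldPlan",
    "FoldMetrics",
    "EvaluationReport",
    "make_folds",
    "mask_fold",
    "roc_auc",
    "pr_auc",
    "threshold_metrics",
    "evaluate_fold",
    "best_f1_threshold",
    "cross_validate",
    "grid_search",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class CVFoldPlan:
    """Partition of the positive cells of A into cross-validation folds."""

    n_folds: int
    fold_assignment: Mapping[Cell, int]
    seed: int

    def cells_in_fold(self, fold_index: int) -> list[Cell]:
        if not 0 <= fold_index < self.n_folds:
            raise ConfigurationError(
                f"fold index {fold_index} out of range [0, {self.n_folds})"
            )
        return sorted(c for c, f in self.fold_assignment.items() if f == fold_index)


@dataclass(frozen=True)
class FoldMetrics:
    auc: float
    aupr: float
    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    threshold: float


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: tuple[FoldMetrics, ...]
    aggregate: Mapping[str, Mapping[str, float]]

    _METRICS = ("auc", "aupr", "acc", "sen", "spe", "pre", "f1")

    @classmethod
    def from_folds(cls, per_fold: Sequence[FoldMetrics]) -> "EvaluationReport":
        agg = {}
        for name in cls._METRICS:
            vals = np.array([getattr(f, name) for f in per_fold])
            agg[name] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=0))}
        return cls(tuple(per_fold), agg)

    def to_frame(self) -> pd.DataFrame:
        """Fold-level metrics as a DataFrame (one row per fold)."""
        rows = [dataclasses.asdict(f) for f in self.per_fold]
        frame = pd.DataFrame(rows)
        frame.insert(0, "fold", range(len(self.per_fold)))
        return frame

    def to_dict(self) -> dict:
        return {
            "per_fold": [dataclasses.asdict(f) for f in self.per_fold],
            "aggregate": {k: dict(v) for k, v in self.aggregate.items()},
        }


def make_folds(A: AssociationMatrix, n_folds: int, seed: int) -> CVFoldPlan:
    """Randomly partition the A = 1 cells into balanced folds.

    Fold sizes differ by at most one; the partition is deterministic
    given the seed.
    """
    if n_folds < 2:
        raise ConfigurationError(f"n_folds must be >= 2, got {n_folds}")
    positives = A.positive_cells()
    if len(positives) < n_folds:
        raise ConfigurationError(
            f"only {len(positives)} known associations but {n_folds} folds requested"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    assignment = {positives[int(p)]: i % n_folds for i, p in enumerate(order)}
    return CVFoldPlan(n_folds, assignment, seed)


def mask_fold(
    A: AssociationMatrix, plan: CVFoldPlan, fold_index: int
) -> AssociationMatrix:
    """Copy of A with the given fold's positives hidden as 0 for training."""
    masked = A.values.copy()
    for i, j in plan.cells_in_fold(fold_index):
        masked[i, j] = 0.0
    return AssociationMatrix(masked, A.drug_ids, A.disease_ids)


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.int64).ravel()
    if s.size == 0:
        raise UndefinedMetricError("empty score/label input")
    if s.shape != y.shape:
        raise UndefinedMetricError("scores and labels differ in length")
    return s, y


def roc_auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney U statistic normalized by (#pos * #neg);
    tied score pairs contribute half credit.
    """
    s, y = _as_arrays(scores, labels)
    if y.min() == y.max():
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(y, s))


def pr_auc(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Area under the precision-recall step curve.

    Step-wise summation over every distinct score threshold (no
    interpolation): sum over thresholds of (recall increment) x precision.
    With all scores tied, this is the positive prevalence.
    """
    s, y = _as_arrays(scores, labels)
    if y.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive label")
    return float(average_precision_score(y, s))


def threshold_metrics(
    scores: Iterable[float], labels: Iterable[int], threshold: float
) -> dict:
    """Confusion-matrix metrics at a fixed threshold (prediction = score >= t).

    Returns acc, sen, spe, pre, f1 together with the raw TP/FP/TN/FN
    counts.  A metric whose denominator is zero is reported as 0.0 and
    its name is listed under ``"undefined"``.
    """
    s, y = _as_arrays(scores, labels)
    if not np.isfinite(threshold):
        raise UndefinedMetricError("threshold must be finite")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    acc = (tp + tn) / len(y)
    pre = ratio(tp, tp + fp, "pre")
    if pre + sen == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return {
        "acc": acc,
        "sen": sen,
        "spe": spe,
        "pre": pre,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "undefined": tuple(undefined),
    }


def best_f1_threshold(scores: Iterable[float], labels: Iterable[int]) -> float:
    """Threshold (among the distinct scores) that maximizes F1.

    Candidates are the distinct observed scores, scanned from high to
    low; ties in F1 keep the highest threshold, so the choice is
    deterministic.
    """
    s, y = _as_arrays(scores, labels)
    if y.sum() == 0:
        raise UndefinedMetricError("F1 threshold needs at least one positive label")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    n_pos = int(y.sum())
    # distinct-score boundaries: last index of each run of equal scores
    last_of_run = np.nonzero(np.diff(s_sorted))[0]
    boundaries = np.append(last_of_run, len(s_sorted) - 1)
    tp = cum_tp[boundaries]
    predicted = boundaries + 1
    precision = tp / predicted
    recall = tp / n_pos
    with np.errstate(invalid="ignore"):
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    best = int(np.argmax(f1))  # first (= highest-threshold) maximum
    return float(s_sorted[boundaries[best]])


def evaluate_fold(
    A: AssociationMatrix,
    held_out: Sequence[Cell],
    scores: np.ndarray,
) -> FoldMetrics:
    """Score a fold: held-out positives vs. every cell unknown in the full A."""
    neg_cells = np.argwhere(A.values == 0.0)
    test_scores = np.concatenate(
        [
            np.array([scores[i, j] for i, j in held_out]),
            scores[neg_cells[:, 0], neg_cells[:, 1]],
        ]
    )
    test_labels = np.concatenate(
        [np.ones(len(held_out), dtype=int), np.zeros(len(neg_cells), dtype=int)]
    )
    thr = best_f1_threshold(test_scores, test_labels)
    tm = threshold_metrics(test_scores, test_labels, thr)
    return FoldMetrics(
        auc=roc_auc(test_scores, test_labels),
        aupr=pr_auc(test_scores, test_labels),
        acc=tm["acc"],
        sen=tm["sen"],
        spe=tm["spe"],
        pre=tm["pre"],
        f1=tm["f1"],
        threshold=thr,
    )


def cross_validate(
    A: AssociationMatrix,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    h: Hyperparameters,
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """K-fold cross-validation over the known associations.

    For each fold the model is refit on the masked matrix and every cell
    is scored; the test pool is the fold's held-out positives plus all
    cells unknown in the full matrix (training positives are excluded).
    The classification threshold for the confusion metrics is chosen per
    fold to maximize F1 and is recorded in the report.
    """
    plan = make_folds(A, n_folds, seed)
    per_fold = []
    for fold in range(n_folds):
        masked = mask_fold(A, plan, fold)
        factors, _ = model.fit(masked, Sd, Se, h)
        scores = factors.X.T @ factors.Y
        per_fold.append(evaluate_fold(A, plan.cells_in_fold(fold), scores))
    return EvaluationReport.from_folds(per_fold)


def grid_search(
    A: AssociationMatrix,
    Sd: SimilarityMatrix,
    Se: SimilarityMatrix,
    base: Hyperparameters,
    grid: Mapping[str, Sequence],
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated AUC over a hyperparameter grid.

    ``grid`` maps Hyperparameters field names (e.g. ``k``, ``mu``,
    ``lam``) to candidate values; every combination is evaluated by
    :func:`cross_validate` and the mean AUC/AUPR recorded.  Rows are
    sorted by descending mean AUC.
    """
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[name] for name in names)):
        h = dataclasses.replace(base, **dict(zip(names, combo)))
        report = cross_validate(A, Sd, Se, h, n_folds=n_folds, seed=seed)
        row = dict(zip(names, combo))
        row["mean_auc"] = report.aggregate["auc"]["mean"]
        row["mean_aupr"] = report.aggregate["aupr"]["mean"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean_auc", ascending=False, ignore_index=True)
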