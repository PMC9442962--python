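"""Semi-supervised label propagation, classification metrics, and
cross-dataset aggregate ranking.

Label propagation diffuses class probabilities over the integrated k-NN
graph: training rows start one-hot and are clamped after every iteration,
unlabeled rows are updated by the row-normalized random walk, and
iteration stops when the largest entry change falls below a threshold
delta (0.001 by default).  Predictions are scored with F1, balanced
accuracy and (rank-based) AUC; dataset-level medians are min-max scaled
within each dataset and averaged into a cross-dataset method ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bundle import NeighborGraph
from .graphs import row_normalize, symmetrize


@dataclass
class ClassificationTask:
    graph: NeighborGraph
    y: np.ndarray
    train_frac: float = 0.5
    delta: float = 0.001
    n_inits: int = 10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.y) != self.graph.n_cells:
            raise ValueError("labels must cover all cells")


@dataclass
class ClassReport:
    metrics: pd.DataFrame  # columns: replicate, F1, acc_b, AUC
    probabilities: np.ndarray  # last replicate's per-cell class probabilities
    classes: np.ndarray
    flags: Dict = field(default_factory=dict)


class ConvergenceError(RuntimeError):
    pass


def stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean train mask preserving class proportions; every class is
    represented in the training set."""
    y = np.asarray(y)
    mask = np.zeros(len(y), dtype=bool)
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        n_train = max(1, int(round(train_frac * len(idx))))
        if n_train >= len(idx) and len(idx) > 1:
            n_train = len(idx) - 1
        mask[rng.choice(idx, size=n_train, replace=False)] = True
    return mask


def propagate_labels(
    graph: NeighborGraph,
    y: Sequence,
    train_mask: np.ndarray,
    delta: float = 0.001,
    max_iter: int = 10_000,
):
    """Diffuse clamped training labels to convergence.

    Returns ``(probabilities, classes, unreachable_mask)``; cells in
    components without any labeled cell receive uniform probabilities.
    """
    y = np.asarray(y)
    train_mask = np.asarray(train_mask, dtype=bool)
    classes = np.unique(y[train_mask])
    if classes.size == 0:
        raise ValueError("training set is empty")
    n = graph.n_cells
    C = classes.size
    P = row_normalize(symmetrize(graph))

    F = np.zeros((n, C))
    onehot = (y[train_mask, None] == classes[None, :]).astype(float)
    F[train_mask] = onehot

    for _ in range(max_iter):
        F_new = P @ F
        sums = F_new.sum(axis=1)
        nz = sums > 0
        F_new[nz] = F_new[nz] / sums[nz, None]
        F_new[train_mask] = onehot
        change = np.abs(F_new - F).max()
        F = F_new
        if change < delta:
            break
    else:
        raise ConvergenceError(
            f"label propagation did not reach delta={delta} within {max_iter} iterations"
        )

    unreachable = F.sum(axis=1) == 0
    if unreachable.any():
        F[unreachable] = 1.0 / C
    return F, classes, unreachable


def label_propagation(task: ClassificationTask, seed: int = 0) -> ClassReport:
    """Run ``n_inits`` stratified train/test splits and score each.

    The converged solution on the unlabeled block coincides with the
    harmonic (absorbing random walk) solution of the graph; metrics are
    computed on the held-out cells only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    probs = None
    classes = None
    any_unreachable = False
    for rep in range(task.n_inits):
        train = stratified_split(task.y, task.train_frac, rng)
        F, classes, unreachable = propagate_labels(
            task.graph, task.y, train, delta=task.delta, max_iter=task.max_iter
        )
        any_unreachable |= bool(unreachable.any())
        test = ~train
        rep_metrics = compute_metrics(task.y[test], F[test], classes)
        rows.append({"replicate": rep, **rep_metrics})
        probs = F
    return ClassReport(
        metrics=pd.DataFrame(rows),
        probabilities=probs,
        classes=classes,
        flags={"unreachable_cells": any_unreachable},
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _rank_auc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC of binary labels vs continuous scores."""
    n_pos = int(y_bin.sum())
    n_neg = len(y_bin) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[y_bin.astype(bool)].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(y_true: Sequence, y_prob: np.ndarray, classes: Optional[np.ndarray] = None) -> Dict[str, float]:
    """F1, balanced accuracy, and AUC from soft class probabilities.

    Binary problems treat the second sorted class as positive (so a
    control/perturbed labeling scores the perturbed class); multiclass F1
    is macro-averaged, balanced accuracy is the mean per-class sensitivity,
    and AUC is one-vs-rest macro-averaged from the probability columns.
    Predicted labels are the argmax with ties broken toward the lower
    class index.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    pred = classes[np.argmax(y_prob, axis=1)]  # argmax takes the first max

    def f1_for(c) -> float:
        tp = np.sum((pred == c) & (y_true == c))
        fp = np.sum((pred == c) & (y_true != c))
        fn = np.sum((pred != c) & (y_true == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    def recall_for(c) -> float:
        m = y_true == c
        return float(np.mean(pred[m] == c)) if m.any() else np.nan

    present = [c for c in classes if (y_true == c).any()]
    if classes.size == 2:
        pos = classes[1]
        f1 = f1_for(pos)
        sens = recall_for(pos)
        neg = classes[0]
        spec = recall_for(neg)
        acc_b = np.nanmean([sens, spec])
        auc = _rank_auc((y_true == pos).astype(float), y_prob[:, 1])
    else:
        f1 = float(np.mean([f1_for(c) for c in present]))
        acc_b = float(np.nanmean([recall_for(c) for c in present]))
        aucs = [
            _rank_auc((y_true == c).astype(float), y_prob[:, i])
            for i, c in enumerate(classes)
        ]
        aucs = [a for a in aucs if np.isfinite(a)]
        auc = float(np.mean(aucs)) if aucs else np.nan
    return {"F1": float(f1), "acc_b": float(acc_b), "AUC": float(auc)}


# ---------------------------------------------------------------------------
# aggregate ranking
# ---------------------------------------------------------------------------

def aggregate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-dataset method ranking from a long-format score table.

    Expects columns ``method, dataset, task, metric, replicate, value``.
    Per (dataset, task, metric), method scores are the median over
    replicates, min-max scaled across methods (all-tied datasets score 0.5
    for every method and are flagged); scaled scores are averaged across
    datasets and ranked descending (rank 1 = best).
    """
    required = {"method", "dataset", "task", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    med = (
        table.groupby(["dataset", "task", "metric", "method"])["value"]
        .median()
        .reset_index()
    )

    def scale(group: pd.DataFrame) -> pd.DataFrame:
        v = group["value"]
        span = v.max() - v.min()
        if span == 0:
            group = group.assign(scaled=0.5, tied=True)
        else:
            group = group.assign(scaled=(v - v.min()) / span, tied=False)
        return group

    med = (
        med.groupby(["dataset", "task", "metric"], group_keys=False)[med.columns]
        .apply(scale)
        .reset_index(drop=True)
    )
    agg = (
        med.groupby(["task", "metric", "method"])
        .agg(score=("scaled", "mean"), tied=("tied", "any"))
        .reset_index()
    )
    agg["rank"] = agg.groupby(["task", "metric"])["score"].rank(
        ascending=False, method="min"
    ).astype(int)
    return agg.sort_values(["task", "metric", "rank"]).reset_index(drop=True)
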