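"""Evaluation metrics for node-level essentiality prediction.

Threshold metrics (recall, MCC, F1, PPV) are computed from a 2x2 confusion
table on a held-out index set; AUROC uses the rank-statistic formulation
(probability that a random positive outscores a random negative, midranks
for ties); Top-N counts assess the full ranking, matching the screening
use case where only the highest-scored candidates are validated.  All
zero-denominator cases return 0 by convention — heavily imbalanced sets
hit them routinely.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "mcc",
    "ppv_recall_f1",
    "auc_score",
    "top_n_counts",
    "degree_baseline",
    "evaluate_predictions",
]

DEFAULT_TOP_N = (100, 200, 300, 400, 500, 600)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsReport:
    auc: float
    recall: float
    mcc: float
    f1: float
    ppv: float
    top_n: dict[int, int]

    def as_dict(self) -> dict:
        out = {"auc": self.auc, "recall": self.recall, "mcc": self.mcc,
               "f1": self.f1, "ppv": self.ppv}
        out.update({f"top_{n}": c for n, c in self.top_n.items()})
        return out


def confusion(hard_labels, true_labels, eval_idx=None) -> ConfusionCounts:
    hard = np.asarray(hard_labels).astype(np.int64)
    true = np.asarray(true_labels).astype(np.int64)
    if hard.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    if eval_idx is not None:
        eval_idx = np.asarray(eval_idx)
        if eval_idx.size == 0:
            raise ValueError("eval_idx must be nonempty")
        if eval_idx.min() < 0 or eval_idx.max() >= hard.size:
            raise IndexError("eval_idx out of range")
        hard, true = hard[eval_idx], true[eval_idx]
    return ConfusionCounts(
        tp=int(np.sum((hard == 1) & (true == 1))),
        fp=int(np.sum((hard == 1) & (true == 0))),
        tn=int(np.sum((hard == 0) & (true == 0))),
        fn=int(np.sum((hard == 0) & (true == 1))),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def ppv_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    ppv = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * ppv * rec / (ppv + rec) if ppv + rec else 0.0
    return float(ppv), float(rec), float(f1)


def auc_score(scores, true_labels, eval_idx=None) -> float:
    """AUROC via the Mann-Whitney rank statistic with midranks for ties.

    Returns NaN (with a warning) when the evaluation set is single-class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true_labels).astype(np.int64)
    if eval_idx is not None:
        scores, true = scores[np.asarray(eval_idx)], true[np.asarray(eval_idx)]
    n_pos = int(true.sum())
    n_neg = true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUROC undefined for a single-class evaluation set",
                      stacklevel=2)
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def top_n_counts(ranking, true_labels, n_values=DEFAULT_TOP_N) -> dict[int, int]:
    """Number of true essentials among the first N ranked nodes, per N."""
    ranking = np.asarray(ranking)
    true = np.asarray(true_labels).astype(np.int64)
    if sorted(ranking.tolist()) != list(range(true.size)):
        raise ValueError("ranking must be a permutation of all node indices")
    prefix = np.cumsum(true[ranking])
    out = {}
    for n in n_values:
        if n > true.size:
            warnings.warn(f"top-N {n} exceeds node count {true.size}; clamped",
                          stacklevel=2)
        out[int(n)] = int(prefix[min(n, true.size) - 1]) if n >= 1 else 0
    return out


def degree_baseline(adjacency_or_edges, n_nodes: int | None = None) -> np.ndarray:
    """Degree-centrality ranking: descending degree, ties by ascending index."""
    arr = np.asarray(adjacency_or_edges)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and (n_nodes is None or n_nodes == arr.shape[0]):
        degrees = arr.sum(axis=1)
    else:
        if n_nodes is None:
            raise ValueError("n_nodes required for an edge-list input")
        degrees = np.zeros(n_nodes, dtype=np.int64)
        for i, j in arr.reshape(-1, 2):
            degrees[i] += 1
            degrees[j] += 1
    return np.lexsort((np.arange(degrees.size), -degrees))


def evaluate_predictions(probabilities, true_labels, eval_idx, ranking=None,
                         delta: float = 0.5,
                         n_values=DEFAULT_TOP_N) -> MetricsReport:
    """Full metric suite: threshold metrics and AUROC on `eval_idx`, Top-N
    on the full-set ranking (screening protocol)."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    hard = (probabilities >= delta).astype(np.int64)
    counts = confusion(hard, true_labels, eval_idx)
    ppv, rec, f1 = ppv_recall_f1(counts)
    if ranking is None:
        ranking = np.lexsort((np.arange(probabilities.size), -probabilities))
    n_values = [n for n in n_values if n <= probabilities.size] or [probabilities.size]
    return MetricsReport(
        auc=auc_score(probabilities, true_labels, eval_idx),
        recall=rec, mcc=mcc(counts), f1=f1, ppv=ppv,
        top_n=top_n_counts(ranking, true_labels, n_values),
    )
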