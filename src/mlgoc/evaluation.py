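"""Object-matching evaluation: Hungarian assignment on reciprocal overlaps.

Predicted and ground-truth objects are matched by solving an assignment
problem whose cost for an eligible pair (overlap > 0) is the reciprocal
of the overlap area; pairs with no overlap are ineligible.  Maximum
cardinality over eligible pairs is enforced first (otherwise leaving
everything unmatched would trivially minimise the total reciprocal
weight), then the total weight is minimised.  From the matching come
object-level precision and recall and the pixel-level accuracy, the
mean Jaccard index over matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .extraction import InstanceSet

__all__ = ["MatchReport", "overlap_matrix", "match_instances", "pixel_accuracy"]


@dataclass
class MatchReport:
    pairs: list = dataclass_field(default_factory=list)  # (pred, truth, overlap, jaccard)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = float("nan")
    recall: float = float("nan")
    mean_jaccard: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "mean_jaccard": self.mean_jaccard,
            "pairs": [
                {"pred": int(p), "truth": int(t), "overlap": int(o), "jaccard": float(j)}
                for p, t, o, j in self.pairs
            ],
        }


def _check_same_grid(pred: InstanceSet, truth: InstanceSet):
    if len(pred) and len(truth) and pred.grid_shape != truth.grid_shape:
        raise ValueError(
            f"grid shapes differ: {pred.grid_shape} vs {truth.grid_shape}"
        )


def overlap_matrix(pred: InstanceSet, truth: InstanceSet) -> np.ndarray:
    """Pairwise intersection areas in pixels, shape (n_pred, n_truth)."""
    _check_same_grid(pred, truth)
    out = np.zeros((len(pred), len(truth)), dtype=np.int64)
    for i, pm in enumerate(pred.masks):
        for j, tm in enumerate(truth.masks):
            out[i, j] = int(np.count_nonzero(pm & tm))
    return out


def match_instances(pred: InstanceSet, truth: InstanceSet) -> MatchReport:
    """Hungarian matching under reciprocal-overlap costs (see module doc)."""
    ov = overlap_matrix(pred, truth)
    n_pred, n_truth = ov.shape
    report = MatchReport()
    if n_pred and n_truth and ov.any():
        cost = np.where(ov > 0, 1.0 / np.maximum(ov, 1), 0.0)
        # ineligible pairs: finite cost exceeding any feasible total of
        # eligible costs (each eligible cost <= 1), so cardinality on
        # eligible edges is maximised first
        big = min(n_pred, n_truth) + 2.0
        cost[ov == 0] = big
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if ov[i, j] <= 0:
                continue
            inter = int(ov[i, j])
            union = int(np.count_nonzero(pred.masks[i] | truth.masks[j]))
            report.pairs.append((int(i), int(j), inter, inter / union))
    report.pairs.sort()
    report.tp = len(report.pairs)
    report.fp = n_pred - report.tp
    report.fn = n_truth - report.tp
    if n_pred > 0:
        report.precision = report.tp / n_pred
    if n_truth > 0:
        report.recall = report.tp / n_truth
    if report.pairs:
        report.mean_jaccard = float(np.mean([p[3] for p in report.pairs]))
    return report


def pixel_accuracy(pred: InstanceSet, truth: InstanceSet) -> float:
    """Mean Jaccard index over matched pairs; NaN when nothing matches."""
    return match_instances(pred, truth).mean_jaccard
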