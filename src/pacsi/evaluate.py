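"""Benchmark scoring against ground truth: ROC-AUC and PR-AUPR.

AUC follows the Mann–Whitney convention (trapezoidal with midrank ties);
the PR area is average precision (step-wise, no interpolation).  Cells with
an undefined distance (empty network module) are excluded from evaluation
and counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sklearn.metrics

from .proximity import ProximityResult

__all__ = ["EvaluationReport", "roc_auc", "pr_auc", "evaluate_run"]


@dataclass
class EvaluationReport:
    auc: float
    aupr: float
    n_positive: int
    n_total: int
    n_excluded: int = 0
    roc_points: list[tuple[float, float]] = field(default_factory=list, repr=False)
    pr_points: list[tuple[float, float]] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr,
                "n_positive": self.n_positive, "n_total": self.n_total,
                "n_excluded": self.n_excluded}


def _check_inputs(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D vectors")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present in truth")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; exclude undefined cells first")
    return scores, truth


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve (Mann–Whitney; midrank under ties)."""
    scores, truth = _check_inputs(scores, truth)
    return float(sklearn.metrics.roc_auc_score(truth, scores))


def pr_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the precision–recall curve via average precision."""
    scores, truth = _check_inputs(scores, truth)
    return float(sklearn.metrics.average_precision_score(truth, scores))


def evaluate_run(results: Sequence[ProximityResult],
                 truth: Sequence[bool]) -> EvaluationReport:
    """Score a pipeline run: negative phenotype distance vs ground truth."""
    truth = np.asarray(truth, dtype=bool)
    if len(results) != len(truth):
        raise ValueError(
            f"{len(results)} results but {len(truth)} truth labels")
    dist = np.array([r.phenotype_distance for r in results], dtype=float)
    defined = ~np.isnan(dist)
    n_excluded = int((~defined).sum())
    scores = -dist[defined]
    t = truth[defined]
    auc = roc_auc(scores, t)
    aupr = pr_auc(scores, t)
    fpr, tpr, _ = sklearn.metrics.roc_curve(t, scores)
    prec, rec, _ = sklearn.metrics.precision_recall_curve(t, scores)
    return EvaluationReport(auc=auc, aupr=aupr,
                            n_positive=int(t.sum()), n_total=int(t.size),
                            n_excluded=n_excluded,
                            roc_points=list(zip(fpr.tolist(), tpr.tolist())),
                            pr_points=list(zip(rec.tolist(), prec.tolist())))
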