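"""Decision rule and evaluation metrics.

Predictions are multi-label: every occupied suborganelle cell whose score
reaches its threshold is called, and a called suborganelle triggers its
organelle — only suborganellar scores are ever compared with thresholds,
which keeps the two levels consistent by construction. Binary metrics (ACC,
MCC, recall, precision) follow the standard confusion-count formulas;
undefined denominators yield a flagged missing value (None, rendered NA)
rather than a silent zero. Ranking metrics are the area under the ROC curve
(equal to the Mann-Whitney probability of ranking a positive above a
negative, ties counting one half) and the area under the precision-recall
curve by trapezoidal integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .hierarchy import LabelHierarchy
from .network import ScoreMatrix
from .training import ThresholdSet

__all__ = [
    "PredictionResult",
    "ConfusionCounts",
    "decide",
    "binary_metrics",
    "ranking_metrics",
    "exact_match",
    "per_class_report",
]


@dataclass
class PredictionResult:
    suborganelles: set
    organelles: set
    scores: ScoreMatrix


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def decide(scores: ScoreMatrix, thresholds: ThresholdSet, h: LabelHierarchy,
           fallback: str = "none") -> PredictionResult:
    """Threshold the suborganelle scores into a multi-label prediction.

    fallback="none" may return empty sets; fallback="top1" adds the highest
    scoring occupied cell when nothing reaches its threshold.
    """
    subs, orgs = set(), set()
    for (r, c) in h.occupied:
        if scores.sub_scores[r, c] >= thresholds.get((r, c)):
            subs.add(h.grid[r][c])
            orgs.add(h.organelles[c])
    if not subs and fallback == "top1":
        r, c = max(h.occupied, key=lambda rc: scores.sub_scores[rc[0], rc[1]])
        subs.add(h.grid[r][c])
        orgs.add(h.organelles[c])
    return PredictionResult(suborganelles=subs, organelles=orgs, scores=scores)


def binary_metrics(c: ConfusionCounts) -> dict:
    """ACC, MCC, recall, precision from confusion counts (None where undefined)."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else None
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else None
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    return {"ACC": acc, "MCC": mcc, "recall": recall, "precision": precision}


def ranking_metrics(scores, labels) -> dict:
    """ROC_auc and PR_auc for one binary class; None when a class is absent."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels differ in length")
    if y.min() == y.max():
        return {"ROC_auc": None, "PR_auc": None}
    roc = float(roc_auc_score(y, s))
    precision, recall, _ = precision_recall_curve(y, s)
    order = np.argsort(recall)
    pr = float(np.trapezoid(precision[order], recall[order]))
    return {"ROC_auc": roc, "PR_auc": pr}


def exact_match(preds, truths):
    """Count samples whose predicted organelle set equals the true set."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths differ in length")
    count = sum(
        1
        for p, t in zip(preds, truths)
        if (p.organelles if isinstance(p, PredictionResult) else set(p)) == set(t)
    )
    return count, count / len(preds) if preds else float("nan")


def per_class_report(results, true_org_sets, h: LabelHierarchy,
                     true_sub_sets=None) -> list:
    """One-vs-rest metric rows per organelle (and optionally per suborganelle).

    Returns a list of dicts (level, class, metric values, support) suitable
    for TSV export; missing values stay None.
    """
    rows = []

    def ovr(level, name, called, truth, score_vec):
        tp = sum(1 for c, t in zip(called, truth) if c and t)
        fp = sum(1 for c, t in zip(called, truth) if c and not t)
        fn = sum(1 for c, t in zip(called, truth) if not c and t)
        tn = len(called) - tp - fp - fn
        row = {"level": level, "class": name, "support": sum(truth)}
        row.update(binary_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)))
        row.update(ranking_metrics(score_vec, truth))
        rows.append(row)

    for c, org in enumerate(h.organelles):
        called = [org in r.organelles for r in results]
        truth = [org in t for t in true_org_sets]
        score = [float(r.scores.org_scores[c]) for r in results]
        ovr("organelle", org, called, truth, score)
    if true_sub_sets is not None:
        for (r_i, c_i) in h.occupied:
            name = h.grid[r_i][c_i]
            called = [name in r.suborganelles for r in results]
            truth = [name in t for t in true_sub_sets]
            score = [float(r.scores.sub_scores[r_i, c_i]) for r in results]
            ovr("suborganelle", name, called, truth, score)
    return rows


def write_report(rows, path) -> None:
    cols = ["level", "class", "support", "ACC", "MCC", "recall", "precision",
            "ROC_auc", "PR_auc"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "NA" if row.get(c) is None
                    else (f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c]))
                    for c in cols
                )
                + "\n"
            )
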