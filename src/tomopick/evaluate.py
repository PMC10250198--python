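"""Scoring picks against ground truth.

A pick counts as a true positive when the intersection-over-union of its
bounding cube with a ground-truth cube is strictly greater than ``iou_min``
(default 0.6).  Matching is one-to-one and greedy: picks are visited in
descending similarity order and each claims the still-unmatched truth of
maximal IoU.  Precision, recall and their harmonic mean F1 follow, with the
0/0 convention mapped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MatchResult", "iou", "match_picks", "prf1", "evaluate_classes"]


@dataclass
class MatchResult:
    true_positive: int
    false_positive: int
    false_negative: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.true_positive != len(self.pairs):
            raise ValueError("TP count must equal number of matched pairs")


def iou(center_a, edge_a: float, center_b, edge_b: float) -> float:
    """Intersection over union of two axis-aligned cubes (center + edge)."""
    if edge_a <= 0 or edge_b <= 0:
        raise ValueError("cube edge lengths must be positive")
    inter = 1.0
    for a, b in zip(center_a, center_b):
        lo = max(a - edge_a / 2.0, b - edge_b / 2.0)
        hi = min(a + edge_a / 2.0, b + edge_b / 2.0)
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    union = edge_a**3 + edge_b**3 - inter
    return inter / union


def match_picks(picks, truths, box_len: int, iou_min: float = 0.6,
                similarities=None) -> MatchResult:
    """Greedy one-to-one matching of pick centers to truth centers.

    ``picks``/``truths`` are sequences of (z, y, x) centers; both sides use
    cubes of edge ``box_len``.  The IoU comparison is strict (> iou_min).
    ``similarities`` orders the picks (descending); if omitted, picks are
    taken in the given order.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must be in (0, 1]")
    picks = [tuple(map(float, p)) for p in picks]
    truths = [tuple(map(float, t)) for t in truths]
    order = range(len(picks))
    if similarities is not None:
        order = np.argsort(-np.asarray(similarities, dtype=float), kind="stable")
    matched_truth = set()
    pairs = []
    for pi in order:
        best_j, best_iou = -1, iou_min
        for tj, truth in enumerate(truths):
            if tj in matched_truth:
                continue
            val = iou(picks[pi], box_len, truth, box_len)
            if val > best_iou:
                best_j, best_iou = tj, val
        if best_j >= 0:
            matched_truth.add(best_j)
            pairs.append((int(pi), int(best_j)))
    tp = len(pairs)
    return MatchResult(true_positive=tp,
                       false_positive=len(picks) - tp,
                       false_negative=len(truths) - tp,
                       pairs=pairs)


def prf1(match: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1); every 0/0 is defined as 0."""
    tp, fp, fn = match.true_positive, match.false_positive, match.false_negative
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate_classes(picks_by_class: dict, truths_by_class: dict,
                     box_len: int, iou_min: float = 0.6,
                     similarities_by_class: dict | None = None) -> pd.DataFrame:
    """Per-class counts and scores plus macro- and pooled-average rows.

    Returns a table with one row per class and two summary rows
    (``macro``: mean of per-class P/R/F1; ``pooled``: scores of the summed
    counts).
    """
    rows = []
    totals = np.zeros(3, dtype=int)
    labels = sorted(set(picks_by_class) | set(truths_by_class), key=str)
    for label in labels:
        sims = (similarities_by_class or {}).get(label)
        m = match_picks(picks_by_class.get(label, []),
                        truths_by_class.get(label, []),
                        box_len, iou_min, similarities=sims)
        p, r, f1 = prf1(m)
        totals += (m.true_positive, m.false_positive, m.false_negative)
        rows.append({"class": label, "TP": m.true_positive,
                     "FP": m.false_positive, "FN": m.false_negative,
                     "precision": p, "recall": r, "F1": f1})
    df = pd.DataFrame(rows)
    if len(df):
        macro = {"class": "macro", "TP": int(totals[0]), "FP": int(totals[1]),
                 "FN": int(totals[2]),
                 "precision": df["precision"].mean(),
                 "recall": df["recall"].mean(), "F1": df["F1"].mean()}
        tp, fp, fn = (int(t) for t in totals)
        pp = tp / (tp + fp) if tp + fp else 0.0
        pr = tp / (tp + fn) if tp + fn else 0.0
        pf = 2 * pp * pr / (pp + pr) if pp + pr else 0.0
        pooled = {"class": "pooled", "TP": int(totals[0]), "FP": int(totals[1]),
                  "FN": int(totals[2]), "precision": pp, "recall": pr, "F1": pf}
        df = pd.concat([df, pd.DataFrame([macro, pooled])], ignore_index=True)
    return df
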