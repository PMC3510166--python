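"""Matching and scoring helpers for validating detections against truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["match_points", "precision_recall", "mask_iou"]


def match_points(detected, truth, max_dist: float):
    """One-to-one Hungarian matching of two point sets.

    Returns a list of (detected_index, truth_index) pairs whose
    distance is <= max_dist; unmatched points on either side are
    omitted.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return []
    cost = cdist(detected, truth)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if cost[r, c] <= max_dist]


def precision_recall(detected, truth, max_dist: float) -> tuple[float, float]:
    """Detection precision and recall under Hungarian matching."""
    matches = match_points(detected, truth, max_dist)
    n_det, n_true = len(detected), len(truth)
    precision = len(matches) / n_det if n_det else 1.0
    recall = len(matches) / n_true if n_true else 1.0
    return precision, recall


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
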