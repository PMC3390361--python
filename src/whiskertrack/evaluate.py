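"""Scoring traced/linked output against synthetic ground truth."""

from __future__ import annotations

import numpy as np

from .tracing import point_polyline_distances


def mean_curve_to_backbone_distance(points: np.ndarray, backbone: np.ndarray) -> float:
    """Mean perpendicular distance from curve points to a truth backbone."""
    return float(point_polyline_distances(np.asarray(points), np.asarray(backbone)).mean())


def backbone_coverage(backbone: np.ndarray, curve_points: np.ndarray, tol_px: float) -> float:
    """Fraction of truth backbone samples lying within tol_px of the curve."""
    d = point_polyline_distances(np.asarray(backbone), np.asarray(curve_points))
    return float((d <= tol_px).mean())


def detection_recall(truths, curves_per_frame, tol_px: float = 2.0, min_coverage: float = 0.5):
    """Fraction of visible truth whisker instances covered by a traced curve.

    An instance counts as detected when some curve covers at least
    ``min_coverage`` of its backbone within ``tol_px``.
    Returns (recall, n_detected, n_visible).
    """
    n_visible = 0
    n_detected = 0
    for truth, curves in zip(truths, curves_per_frame):
        for wt in truth["whiskers"]:
            if not wt["visible"]:
                continue
            n_visible += 1
            bb = wt["points"]
            for c in curves:
                if backbone_coverage(bb, c.points, tol_px) >= min_coverage:
                    n_detected += 1
                    break
    recall = n_detected / n_visible if n_visible else float("nan")
    return recall, n_detected, n_visible


def identity_accuracy(
    truths, curves_per_frame, labelings, orders, tol_px: float = 2.0
):
    """Fraction of visible truth instances carrying the right identity.

    Truth whiskers are indexed in anterior-posterior base order, so truth
    whisker i corresponds to label W{i+1}.  An instance is correct when
    exactly one curve holds its label and that curve lies within ``tol_px``
    mean distance of the truth backbone.
    Returns (accuracy, n_correct, n_visible).
    """
    n_visible = 0
    n_correct = 0
    for truth, curves, labeling, order in zip(
        truths, curves_per_frame, labelings, orders
    ):
        label_to_curve = {}
        for pos, lbl in enumerate(labeling.labels):
            if lbl.startswith("W"):
                label_to_curve[lbl] = curves[order[pos]]
        for wi, wt in enumerate(truth["whiskers"]):
            if not wt["visible"]:
                continue
            n_visible += 1
            curve = label_to_curve.get(f"W{wi + 1}")
            if curve is None:
                continue
            if mean_curve_to_backbone_distance(curve.points, wt["points"]) <= tol_px:
                n_correct += 1
    acc = n_correct / n_visible if n_visible else float("nan")
    return acc, n_correct, n_visible
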