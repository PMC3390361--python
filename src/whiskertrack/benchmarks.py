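"""Self-contained benchmark runs used by the acceptance suite and script.

Each function regenerates its synthetic inputs from a seed, runs the
pipeline, and measures the result — nothing is cached or looked up.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .evaluate import detection_recall, identity_accuracy
from .imgproc import preprocess
from .linking import link_video
from .measure import FaceConfig
from .seeding import HALF, evaluate_sites
from .synthdata import benchmark_scene, default_scene, render_frame, single_whisker_scene
from .tracing import get_default_bank, point_polyline_distances, trace_frame

log = logging.getLogger(__name__)


def seed_coverage(seed: int = 0, n_frames: int = 10, ecc_threshold: float = 0.95):
    """Fraction (%) of whisker backbone pixels scoring above the
    eccentricity threshold, over noiseless-to-moderate-noise frames."""
    sigmas = [0.0, 0.5, 1.0, 1.5, 2.0]
    n_hit = 0
    n_total = 0
    for k in range(n_frames):
        scene = default_scene(seed=seed * 1000 + k, noise_sigma=sigmas[k % len(sigmas)])
        frame, truth = render_frame(scene, k)
        h, w = frame.pixels.shape
        pix = set()
        for wt in truth["whiskers"]:
            for x, y in np.round(wt["points"]).astype(int):
                if HALF <= x < w - HALF and HALF <= y < h - HALF:
                    pix.add((x, y))
        if not pix:
            continue
        xs = np.array([p[0] for p in pix])
        ys = np.array([p[1] for p in pix])
        ecc, _, _, _ = evaluate_sites(frame, xs, ys)
        n_hit += int((ecc > ecc_threshold).sum())
        n_total += xs.size
    return 100.0 * n_hit / n_total, n_total


def tracing_accuracy(seed: int = 0):
    """Mean perpendicular distance (px) between traced curves and analytic
    backbones over 39 single-whisker scenes (widths 1-3 px, orientations
    0-90 degrees)."""
    bank = get_default_bank()
    cfg = RunConfig()
    total = 0.0
    count = 0
    n_whiskers = 0
    i = 0
    for width in (1.0, 2.0, 3.0):
        for orientation in np.linspace(3.0, 87.0, 13):
            scene = single_whisker_scene(float(orientation), width, seed=seed * 100 + i)
            i += 1
            frame, truth = render_frame(scene, 0)
            curves = trace_frame(frame, cfg, bank)
            if not curves:
                log.warning("no curve traced at width %.1f orientation %.0f", width, orientation)
                continue
            curve = max(curves, key=lambda c: c.arc_length)
            d = point_polyline_distances(curve.points, truth["whiskers"][0]["points"])
            total += float(d.sum())
            count += d.size
            n_whiskers += 1
    return total / count, n_whiskers


def tracking_benchmark(seed: int = 0, n_frames: int = 2000, n_whiskers=None):
    """Full trace+link run on the tracking benchmark.

    Returns a dict with identity accuracy and detection recall (%), plus the
    learned model summary.
    """
    scene = benchmark_scene(seed=seed)
    bank = get_default_bank()
    cfg = RunConfig()
    truths, curves = [], []
    for t in range(n_frames):
        frame, truth = render_frame(scene, t)
        frame = preprocess(frame, line_bias=cfg.line_bias_correction)
        curves.append(trace_frame(frame, cfg, bank))
        truths.append(truth)
        if t and t % 500 == 0:
            log.info("traced %d/%d frames", t, n_frames)
    face = FaceConfig(face=scene.face_spec())
    labelings, model, orders = link_video(curves, face, N=n_whiskers)
    recall, n_det, n_vis = detection_recall(truths, curves)
    acc, n_corr, n_vis2 = identity_accuracy(truths, curves, labelings, orders)
    return {
        "identity_accuracy_pct": 100.0 * acc,
        "detection_recall_pct": 100.0 * recall,
        "n_visible": n_vis,
        "n_detected": n_det,
        "n_correct": n_corr,
        "n_whiskers": model.heuristic.N,
        "lambda_px": model.heuristic.lambda_px,
        "n_training_frames": len(model.heuristic.training_frames),
    }
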