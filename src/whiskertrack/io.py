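"""Readers and writers for the pipeline's file formats.

Video input: multi-page TIFF or a directory of numbered grayscale images.
Curve output: versioned line-oriented JSON (one record per curve) with an
optional TSV export; measurements go to TSV; truth and configuration to
JSON.  Every writer round-trips losslessly through its reader at the stored
precision.
"""

from __future__ import annotations

import json
import os
import re
from typing import Iterable, Iterator

import numpy as np

from .imgproc import Frame
from .tracing import TracedCurve

CURVES_FORMAT = "whiskertrack-curves"
CURVES_VERSION = 1
TRUTH_FORMAT = "whiskertrack-truth"
FLOAT_DECIMALS = 4


# -- video ----------------------------------------------------------------


def read_video(path, pixel_size_um: float = 1.0) -> Iterator[Frame]:
    """Yield frames from a multi-page TIFF or a directory of numbered images.

    Frames are promoted to real-valued intensities; non-grayscale input is
    rejected, and gaps in a numbered directory are reported explicitly.
    """
    if os.path.isdir(path):
        yield from _read_image_dir(path, pixel_size_um)
        return
    import tifffile

    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"non-grayscale page {i} in {path} (shape {arr.shape})"
                )
            yield Frame(arr.astype(np.float64), i, pixel_size_um)


def _read_image_dir(path, pixel_size_um):
    import imageio.v3 as iio

    entries = []
    for name in sorted(os.listdir(path)):
        m = re.search(r"(\d+)\D*$", name)
        if m and os.path.isfile(os.path.join(path, name)):
            entries.append((int(m.group(1)), name))
    if not entries:
        raise ValueError(f"no numbered image files found in {path}")
    entries.sort()
    numbers = [n for n, _ in entries]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        missing = sorted(set(expected) - set(numbers))
        raise ValueError(f"missing frame numbers in {path}: {missing}")
    for i, (_, name) in enumerate(entries):
        arr = iio.imread(os.path.join(path, name))
        if arr.ndim != 2:
            raise ValueError(f"non-grayscale image {name} (shape {arr.shape})")
        yield Frame(arr.astype(np.float64), i, pixel_size_um)


def write_video_tiff(path, frames: Iterable[Frame]) -> None:
    import tifffile

    stack = np.stack(
        [np.clip(np.rint(f.pixels), 0, 255).astype(np.uint8) for f in frames]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")


# -- curves ---------------------------------------------------------------


def _round_list(values) -> list:
    return [round(float(v), FLOAT_DECIMALS) for v in values]


def write_curves(path, curves_per_frame, labels_per_frame=None) -> None:
    """Line-oriented JSON: a header line, then one record per curve.

    ``labels_per_frame`` optionally adds a "label" field per curve (aligned
    with the curve lists).
    """
    with open(path, "w") as fh:
        fh.write(
            json.dumps(
                {
                    "format": CURVES_FORMAT,
                    "version": CURVES_VERSION,
                    "n_frames": len(curves_per_frame),
                }
            )
            + "\n"
        )
        for t, curves in enumerate(curves_per_frame):
            for ci, c in enumerate(curves):
                rec = {
                    "frame": int(c.frame_index if c.frame_index else t),
                    "curve_id": ci,
                    "x": _round_list(c.points[:, 0]),
                    "y": _round_list(c.points[:, 1]),
                    "score": _round_list(c.scores),
                    "width": _round_list(c.widths),
                }
                rec["frame"] = t
                if labels_per_frame is not None:
                    rec["label"] = labels_per_frame[t][ci]
                fh.write(json.dumps(rec) + "\n")


def read_curves(path):
    """Returns (curves_per_frame, labels_per_frame_or_None)."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != CURVES_FORMAT:
            raise ValueError(f"{path} is not a {CURVES_FORMAT} file")
        if header.get("version") != CURVES_VERSION:
            raise ValueError(f"unsupported curves version {header.get('version')}")
        n_frames = header["n_frames"]
        curves = [[] for _ in range(n_frames)]
        labels = [[] for _ in range(n_frames)]
        any_labels = False
        for line in fh:
            rec = json.loads(line)
            t = rec["frame"]
            curve = TracedCurve(
                np.stack([rec["x"], rec["y"]], axis=1),
                np.array(rec["score"], dtype=np.float64),
                np.array(rec["width"], dtype=np.float64),
                t,
            )
            curves[t].append(curve)
            if "label" in rec:
                any_labels = True
                labels[t].append(rec["label"])
            else:
                labels[t].append(None)
    return curves, (labels if any_labels else None)


def write_curves_tsv(path, curves_per_frame, labels_per_frame=None) -> None:
    """Flat TSV export: one row per traced point."""
    with open(path, "w") as fh:
        cols = ["frame", "curve_id", "point_index", "x", "y", "score", "width"]
        if labels_per_frame is not None:
            cols.append("label")
        fh.write("\t".join(cols) + "\n")
        for t, curves in enumerate(curves_per_frame):
            for ci, c in enumerate(curves):
                for pi in range(c.points.shape[0]):
                    row = [
                        str(t),
                        str(ci),
                        str(pi),
                        f"{c.points[pi, 0]:.4f}",
                        f"{c.points[pi, 1]:.4f}",
                        f"{c.scores[pi]:.4f}",
                        f"{c.widths[pi]:.4f}",
                    ]
                    if labels_per_frame is not None:
                        row.append(str(labels_per_frame[t][ci]))
                    fh.write("\t".join(row) + "\n")


# -- link summary ---------------------------------------------------------


def write_link_summary(path, model) -> None:
    summary = {
        "n_whiskers": model.heuristic.N,
        "lambda_px": round(model.heuristic.lambda_px, FLOAT_DECIMALS),
        "n_training_frames": len(model.heuristic.training_frames),
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


# -- measurements ---------------------------------------------------------

MEASURE_COLUMNS = [
    "frame",
    "label",
    "length_px",
    "angle_deg",
    "curvature_per_mm",
    "follicle_x",
    "follicle_y",
    "tip_x",
    "tip_y",
    "score",
    "contact_x",
    "contact_y",
    "contact_dist_px",
]


def write_measurements(path, records) -> None:
    """TSV, one row per (frame, whisker); missing values are empty fields."""

    def fmt(v):
        return "" if v is None else (f"{v:.4f}" if isinstance(v, float) else str(v))

    with open(path, "w") as fh:
        fh.write("\t".join(MEASURE_COLUMNS) + "\n")
        for r in records:
            cx, cy = (r.contact_point if r.contact_point is not None else (None, None))
            row = [
                str(r.frame),
                r.label,
                f"{r.length_px:.4f}",
                f"{r.angle_at_base_deg:.4f}",
                fmt(r.curvature_per_mm),
                f"{r.follicle[0]:.4f}",
                f"{r.follicle[1]:.4f}",
                f"{r.tip[0]:.4f}",
                f"{r.tip[1]:.4f}",
                f"{r.mean_score:.4f}",
                fmt(cx),
                fmt(cy),
                fmt(r.contact_distance_px),
            ]
            fh.write("\t".join(row) + "\n")


# -- truth ----------------------------------------------------------------


def write_truth(path, scene, truths) -> None:
    doc = {
        "format": TRUTH_FORMAT,
        "version": 1,
        "n_whiskers": scene.n_whiskers,
        "frames": [
            {
                "whiskers": [
                    {
                        "points": [
                            [round(float(x), 2), round(float(y), 2)]
                            for x, y in wt["points"]
                        ],
                        "visible": wt["visible"],
                        "arc_len_px": round(float(wt["arc_len_px"]), 2),
                        "deflection_deg": round(float(wt["deflection_deg"]), 4),
                    }
                    for wt in tr["whiskers"]
                ]
            }
            for tr in truths
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_truth(path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != TRUTH_FORMAT:
        raise ValueError(f"{path} is not a {TRUTH_FORMAT} file")
    truths = []
    for frame in doc["frames"]:
        truths.append(
            {
                "whiskers": [
                    {
                        "points": np.array(wt["points"], dtype=np.float64).reshape(-1, 2),
                        "visible": wt["visible"],
                        "arc_len_px": wt["arc_len_px"],
                        "deflection_deg": wt["deflection_deg"],
                    }
                    for wt in frame["whiskers"]
                ]
            }
        )
    return truths
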