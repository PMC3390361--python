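"""Bidirectional sub-pixel curve growth from seeds.

Tracing initializes the detector at a seed, then repeatedly steps 1 px along
the current tangent, re-optimizing the detector at each step.  Safety
tests guard each step; on failure the tracer linearly extrapolates up to a
maximum gap distance trying to re-acquire the curve (whisker crossings, pole
occlusions), bridging the gap with a straight segment on success and
truncating at the last trusted point otherwise.  Finally, near-duplicate
curves are resolved.  Tracing is stateless across frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import RunConfig
from .detector_bank import DetectorBank, DetectorParams
from .imgproc import Frame
from .seeding import Seed, find_seeds

_SPACING_TOL = 1e-6


@dataclass
class TracedCurve:
    """Ordered polyline of sub-pixel points with per-point score and width."""

    points: np.ndarray  # (N, 2) float, (x, y)
    scores: np.ndarray  # (N,)
    widths: np.ndarray  # (N,)
    frame_index: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.widths = np.asarray(self.widths, dtype=np.float64)
        n = self.points.shape[0]
        if n < 2:
            raise ValueError("TracedCurve needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if (steps <= 0).any() or (steps > 2.0 + _SPACING_TOL).any():
            raise ValueError("consecutive point spacing must be in (0, 2] px")
        if (self.scores < 0).any():
            raise ValueError("scores must be >= 0")

    @property
    def arc_length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum()
        )


@dataclass
class StopTests:
    """Thresholds for the per-step safety tests.

    ``min_score`` is an absolute detector-response threshold;
    ``min_mean_intensity`` is a fraction of the frame mean intensity.
    """

    min_score: float
    max_asymmetry: float = 0.25
    min_mean_intensity: float = 0.35
    max_angle_step_deg: float = 7.5
    max_gap_px: int = 8

    def __post_init__(self):
        for name in (
            "min_score",
            "max_asymmetry",
            "min_mean_intensity",
            "max_angle_step_deg",
            "max_gap_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_frame(cls, frame: Frame, config: RunConfig | None = None) -> "StopTests":
        cfg = config or RunConfig()
        rng = float(frame.pixels.max() - frame.pixels.min())
        return cls(
            min_score=cfg.min_score_frac * max(rng, 1.0),
            max_asymmetry=cfg.max_asymmetry,
            min_mean_intensity=cfg.min_mean_intensity,
            max_angle_step_deg=cfg.max_angle_step_deg,
            max_gap_px=cfg.max_gap_px,
        )


def bilinear_sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with border clamping."""
    h, w = img.shape
    xs = np.clip(xs, 0.0, w - 1.0)
    ys = np.clip(ys, 0.0, h - 1.0)
    x0 = np.clip(np.floor(xs).astype(np.intp), 0, w - 2) if w > 1 else np.zeros_like(xs, np.intp)
    y0 = np.clip(np.floor(ys).astype(np.intp), 0, h - 2) if h > 1 else np.zeros_like(ys, np.intp)
    fx = xs - x0
    fy = ys - y0
    return (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )


_N_LINE_SAMPLES = 21


def step_tests(
    frame: Frame,
    anchor,
    params: DetectorParams,
    score: float,
    prev_angle_deg: float,
    thresholds: StopTests,
    frame_mean: float | None = None,
):
    """The per-step safety tests.

    1. detector score >= min_score;
    2. left/right flank asymmetry |I_L - I_R| / max(I_L + I_R, eps) within
       bound, where the flanks are 20x1 px bands just outside the detector;
    3. mean intensity under the detector footprint at least
       min_mean_intensity x frame mean;
    4. angular change from the previous step within bound (mod 180, folded);
    5. valley: the interpolated intensity at the detector center darker than
       both flank bands.  The long detector support keeps the score high for
       several pixels past an abrupt line end, so the score test alone lets
       traces overrun tips; the center-point valley test stops at the end.

    Returns (ok, failed_test_names).
    """
    img = frame.pixels
    if frame_mean is None:
        frame_mean = float(img.mean())
    failed = []
    if score < thresholds.min_score:
        failed.append("score")

    cx = anchor[0] + params.offset[0]
    cy = anchor[1] + params.offset[1]
    theta = math.radians(params.angle_deg)
    ct, st = math.cos(theta), math.sin(theta)
    hl = params.length_px / 2.0
    hw = params.width_px / 2.0

    flank = hw + 1.5  # center of the 1-px band just outside the detector
    vs = np.array([-flank, flank, -hw - 1.0, -hw, 0.0, hw, hw + 1.0])
    means = _kernels.line_means(img, cx, cy, ct, st, hl, vs, _N_LINE_SAMPLES)
    i_left, i_right = means[0], means[1]
    asym = abs(i_left - i_right) / max(i_left + i_right, 1e-6)
    if asym > thresholds.max_asymmetry:
        failed.append("asymmetry")

    foot = means[2:].mean()
    if foot < thresholds.min_mean_intensity * frame_mean:
        failed.append("mean_intensity")

    center_pt = _kernels.line_means(
        img, cx, cy, ct, st, 1e-6, np.zeros(1), 3
    )[0]
    if center_pt >= min(i_left, i_right) - 0.01 * (i_left + i_right):
        failed.append("valley")

    dang = abs(params.angle_deg - prev_angle_deg) % 180.0
    if dang > 90.0:
        dang = 180.0 - dang
    if dang > thresholds.max_angle_step_deg:
        failed.append("angle_step")

    return (len(failed) == 0), failed


def _is_valley(frame: Frame, anchor, params: DetectorParams, rel_margin: float = 0.02) -> bool:
    """Initialization sanity check: the detector must straddle an intensity
    valley — the center line strictly darker than both flanking bands.

    This rejects 'rider' optima where a wide detector locks onto a dark line
    a few pixels off-axis (one inner band over the core, center on bright
    background), which pass the four step tests but trace parallel ghosts.
    Applied at initiation only; mid-trace occlusions are the step tests' job.
    """
    img = frame.pixels
    cx = anchor[0] + params.offset[0]
    cy = anchor[1] + params.offset[1]
    theta = math.radians(params.angle_deg)
    ct, st = math.cos(theta), math.sin(theta)
    hl = params.length_px / 2.0
    hw = params.width_px / 2.0
    vs = np.array([0.0, -(hw + 1.5), hw + 1.5])
    center, left, right = _kernels.line_means(
        img, cx, cy, ct, st, hl, vs, _N_LINE_SAMPLES
    )
    floor = min(left, right)
    return center < floor - rel_margin * 0.5 * (left + right)


def _in_bounds(pos, shape, margin=0.5):
    h, w = shape
    return margin <= pos[0] <= w - 1.0 - margin and margin <= pos[1] <= h - 1.0 - margin


def _tangent(angle_deg, heading):
    t = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
    if float(t @ heading) < 0.0:
        t = -t
    return t


def trace_from_seed(
    frame: Frame,
    seed: Seed,
    bank: DetectorBank,
    thresholds: StopTests,
    max_points: int = 20000,
):
    """Grow a curve bidirectionally from one seed.

    Returns a TracedCurve, or None when initialization fails the safety
    tests or fewer than 2 points survive.
    """
    img = frame.pixels
    shape = img.shape
    mean_i = float(img.mean())
    anchor = (int(seed.pos[0]), int(seed.pos[1]))

    # Initialization: angle from the seed, width by joint width/offset scan,
    # then a full local optimization.
    p0, _ = bank.scan_widths(frame, anchor, seed.angle_deg)
    best0, score0 = bank.optimize_step(frame, anchor, p0, mean_intensity=mean_i)
    ok, _ = step_tests(
        frame, anchor, best0, score0, best0.angle_deg, thresholds, mean_i
    )
    if not ok or not _is_valley(frame, anchor, best0):
        return None
    pos0 = np.array([anchor[0] + best0.offset[0], anchor[1] + best0.offset[1]])
    if not _in_bounds(pos0, shape):
        return None

    halves = []
    for sign in (1.0, -1.0):
        heading = sign * np.array(
            [math.cos(math.radians(best0.angle_deg)), math.sin(math.radians(best0.angle_deg))]
        )
        halves.append(
            _extend(
                frame, bank, thresholds, pos0, best0, heading, mean_i, max_points
            )
        )

    back = halves[1]
    fwd = halves[0]
    points = [t[0] for t in reversed(back)] + [pos0] + [t[0] for t in fwd]
    scores = [t[1] for t in reversed(back)] + [score0] + [t[1] for t in fwd]
    widths = [t[2] for t in reversed(back)] + [best0.width_px] + [t[2] for t in fwd]
    if len(points) < 2:
        return None
    return TracedCurve(
        np.array(points), np.array(scores), np.array(widths), frame.frame_index
    )


def _extend(frame, bank, thr, pos0, params0, heading0, mean_i, max_points):
    """Grow one half-trace; returns a list of (pos, score, width)."""
    out = []
    pos = pos0.copy()
    params = params0
    heading = heading0.copy()
    shape = frame.pixels.shape
    while len(out) < max_points:
        step = _advance(frame, bank, thr, pos, params, heading, mean_i)
        if step is None:
            # gap mode: linear extrapolation along the last trusted direction
            bridge = _jump_gap(frame, bank, thr, pos, params, heading, mean_i)
            if bridge is None:
                break
            gap_pts, pos, params, heading, score = bridge
            out.extend(gap_pts)
            out.append((pos.copy(), score, params.width_px))
            continue
        pos, params, heading, score = step
        out.append((pos.copy(), score, params.width_px))
    return out


def _advance(frame, bank, thr, pos, params, heading, mean_i):
    """One 1-px step along the tangent; None when a safety test fails."""
    target = pos + heading
    if not _in_bounds(target, frame.pixels.shape):
        return None
    anchor = (int(round(target[0])), int(round(target[1])))
    pred = (target[0] - anchor[0], target[1] - anchor[1])
    best, score, anchor = bank.optimize_local(
        frame, anchor, params, pred, mean_i, width_window=1
    )
    ok, _ = step_tests(
        frame, anchor, best, score, params.angle_deg, thr, mean_i
    )
    if not ok:
        return None
    new_pos = np.array([anchor[0] + best.offset[0], anchor[1] + best.offset[1]])
    adv = float((new_pos - pos) @ heading)
    if adv < 0.25:  # refuses to move forward: treat as untrusted
        return None
    return new_pos, best, _tangent(best.angle_deg, heading), score


def _jump_gap(frame, bank, thr, pos, params, heading, mean_i):
    """Linear 1-px steps along the trusted direction, up to max_gap_px.

    On re-acquisition returns (bridge_points, pos, params, heading, score);
    bridge points carry score 0 and the trusted width.
    """
    shape = frame.pixels.shape
    for g in range(1, thr.max_gap_px + 1):
        q = pos + g * heading
        if not _in_bounds(q, shape):
            return None
        anchor = (int(round(q[0])), int(round(q[1])))
        pred = (q[0] - anchor[0], q[1] - anchor[1])
        best, score, anchor = bank.optimize_local(
            frame, anchor, params, pred, mean_i, width_window=1
        )
        ok, _ = step_tests(frame, anchor, best, score, params.angle_deg, thr, mean_i)
        if not ok:
            continue
        # re-acquisition must land on a genuine valley; without this the
        # detector's long support lets traces crawl past abrupt line ends
        if not _is_valley(frame, anchor, best):
            continue
        new_pos = np.array([anchor[0] + best.offset[0], anchor[1] + best.offset[1]])
        if float((new_pos - pos) @ heading) < 0.25:
            continue
        bridge = [
            (pos + k * heading, 0.0, params.width_px) for k in range(1, g)
        ]
        # drop bridge points that would land past the re-acquired position
        bridge = [
            (p, s, w)
            for p, s, w in bridge
            if float((new_pos - p) @ heading) > 0.25
        ]
        return bridge, new_pos, best, _tangent(best.angle_deg, heading), score
    return None


# -- redundant-curve resolution ------------------------------------------


def point_polyline_distances(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Exact distance from each point to the nearest segment of a polyline."""
    pts = np.asarray(pts, dtype=np.float64)
    poly = np.asarray(poly, dtype=np.float64)
    if poly.shape[0] == 1:
        return np.linalg.norm(pts - poly[0], axis=1)
    a = poly[:-1]
    d = poly[1:] - a
    len2 = (d * d).sum(axis=1)
    len2[len2 == 0] = 1e-30
    # (n_pts, n_seg)
    diff = pts[:, None, :] - a[None, :, :]
    t = np.clip((diff * d[None, :, :]).sum(axis=2) / len2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    return np.linalg.norm(pts[:, None, :] - proj, axis=2).min(axis=1)


def _max_covered_run(curve: TracedCurve, other: TracedCurve, dist_px: float) -> float:
    """Arc length of the longest contiguous interval of ``curve`` whose points
    all lie within dist_px of ``other``."""
    d = point_polyline_distances(curve.points, other.points)
    close = d <= dist_px
    if not close.any():
        return 0.0
    seg = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    best = 0.0
    i = 0
    n = close.size
    while i < n:
        if close[i]:
            j = i
            while j + 1 < n and close[j + 1]:
                j += 1
            best = max(best, s[j] - s[i])
            i = j + 1
        else:
            i += 1
    return best


def _raster_pixels(curve: TracedCurve, shape):
    h, w = shape
    xs = np.clip(np.round(curve.points[:, 0]).astype(int), 0, w - 1)
    ys = np.clip(np.round(curve.points[:, 1]).astype(int), 0, h - 1)
    px = set()
    for x, y in zip(xs, ys):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                px.add((x + dx, y + dy))
    return px


def remove_redundant(curves, dist_px: float = 2.0, frac: float = 0.5):
    """Discard near-duplicate traces until a fixed point is reached.

    A curve is redundant when a contiguous interval lying within ``dist_px``
    of another curve covers more than ``frac`` of its arc length; the shorter
    of the pair (ties: the later in input order) is dropped.
    """
    if dist_px <= 0:
        raise ValueError("dist_px must be > 0")
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    work = list(curves)
    if not work:
        return []
    shape_hint = (
        int(max(c.points[:, 1].max() for c in work)) + 3,
        int(max(c.points[:, 0].max() for c in work)) + 3,
    )
    changed = True
    while changed:
        changed = False
        rasters = [_raster_pixels(c, shape_hint) for c in work]
        n = len(work)
        for i in range(n):
            for j in range(i + 1, n):
                if not (rasters[i] & rasters[j]):
                    continue
                li = work[i].arc_length
                lj = work[j].arc_length
                red_i = _max_covered_run(work[i], work[j], dist_px) > frac * li
                red_j = _max_covered_run(work[j], work[i], dist_px) > frac * lj
                if red_i or red_j:
                    # drop the shorter; ties drop the later in input order
                    drop = j if lj < li or (lj == li) else i
                    del work[drop]
                    changed = True
                    break
            if changed:
                break
    return work


# -- per-frame driver ----------------------------------------------------

_DEFAULT_BANK = None


def get_default_bank() -> DetectorBank:
    global _DEFAULT_BANK
    if _DEFAULT_BANK is None:
        _DEFAULT_BANK = DetectorBank()
    return _DEFAULT_BANK


def trace_frame(
    frame: Frame,
    config: RunConfig | None = None,
    bank: DetectorBank | None = None,
):
    """Seeds -> traces -> dedup for one (already preprocessed) frame.

    Deterministic for a fixed input and configuration.  Seeds are consumed
    in descending eccentricity; seeds within 1 px of an already-traced curve
    are skipped.
    """
    cfg = config or RunConfig()
    bank = bank or get_default_bank()
    seeds = find_seeds(frame, cfg.grid_spacing_px, cfg.ecc_threshold)
    thr = StopTests.from_frame(frame, cfg)
    h, w = frame.pixels.shape
    mask = np.zeros((h, w), dtype=bool)
    curves = []
    for seed in seeds:
        x, y = seed.pos
        if mask[y, x]:
            continue
        curve = trace_from_seed(frame, seed, bank, thr)
        if curve is None:
            continue
        curves.append(curve)
        xs = np.clip(np.round(curve.points[:, 0]).astype(int), 1, w - 2)
        ys = np.clip(np.round(curve.points[:, 1]).astype(int), 1, h - 2)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                mask[ys + dy, xs + dx] = True
    return remove_redundant(curves, cfg.dedup_dist_px, cfg.dedup_frac)
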