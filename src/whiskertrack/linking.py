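"""Whisker identity assignment across a video.

Strategy: a length-threshold heuristic picks training frames where exactly N
long curves appear; those frames train (a) per-feature shape histograms for
whisker vs false-positive curves, (b) label-transition counts for the
ordered-label chain, and (c) frame-to-frame feature-change histograms.  Each
frame is then labeled by exact dynamic programming over the 2N+1 ordered
labels (W1..WN, F0..FN), and labelings propagate from the most confident
frames outward until every frame is visited.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .measure import FaceConfig, curvature_at, fit_parametric

log = logging.getLogger(__name__)

N_FEATURES = 6
N_BINS = 32


@dataclass(frozen=True)
class CurveFeatures:
    """The six scalar features used by the linker."""

    angle_at_face_deg: float
    mean_curvature_per_px: float
    mean_score: float
    length_px: float
    endpoint_follicle: float  # AP coordinate of the face-side endpoint
    endpoint_tip: float  # AP coordinate of the distal endpoint

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.angle_at_face_deg,
                self.mean_curvature_per_px,
                self.mean_score,
                self.length_px,
                self.endpoint_follicle,
                self.endpoint_tip,
            ]
        )


def compute_features(curve, face: FaceConfig) -> CurveFeatures:
    """Features of one traced curve.

    Angle and curvature come from a degree-3 parametric fit (chord angle and
    zero curvature when fewer than 4 points are available).
    """
    pts = np.asarray(curve.points, dtype=np.float64)
    scores = np.asarray(curve.scores, dtype=np.float64)
    d0 = float(face.face_distance(pts[0]))
    d1 = float(face.face_distance(pts[-1]))
    if d1 < d0:
        pts = pts[::-1]
        scores = scores[::-1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    if pts.shape[0] >= 4 and length > 0:
        poly = fit_parametric(pts, 3)
        dx, dy, _, _ = poly.derivatives(0.0)
        angle = face.angle_from_tangent((float(dx), float(dy)), pts[0])
        t = np.linspace(0.0, 1.0, 64)
        try:
            curv = float(np.mean(np.abs(curvature_at(poly, t))))
        except ValueError:
            curv = 0.0
    else:
        tan = pts[-1] - pts[0]
        angle = face.angle_from_tangent(tan, pts[0])
        curv = 0.0
    return CurveFeatures(
        angle_at_face_deg=float(angle),
        mean_curvature_per_px=curv,
        mean_score=float(scores.mean()),
        length_px=length,
        endpoint_follicle=float(face.ap_position(pts[0])),
        endpoint_tip=float(face.ap_position(pts[-1])),
    )


# -- length-threshold heuristic ------------------------------------------


@dataclass
class ThresholdHeuristic:
    N: int
    lambda_px: float
    training_frames: set

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")


def _frame_lengths(all_curves):
    out = []
    for frame_curves in all_curves:
        lens = []
        for c in frame_curves:
            if isinstance(c, CurveFeatures):
                lens.append(c.length_px)
            elif hasattr(c, "arc_length"):
                lens.append(c.arc_length)
            else:
                lens.append(float(c))
        out.append(np.sort(np.asarray(lens, dtype=np.float64)))
    return out


def candidate_thresholds(lengths: np.ndarray, max_candidates: int = 4096):
    """Midpoints between consecutive distinct observed lengths, plus 0 and
    max+1, with the width of the length gap each midpoint sits in.  Very
    large inputs are thinned to quantile-spaced candidates."""
    uniq = np.unique(lengths)
    if uniq.size == 0:
        return np.array([0.0]), np.array([0.0])
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    gaps = np.diff(uniq) if uniq.size > 1 else np.empty(0)
    cands = np.concatenate([[0.0], mids, [uniq[-1] + 1.0]])
    widths = np.concatenate([[uniq[0]], gaps, [1.0]])
    if cands.size > max_candidates:
        idx = np.unique(np.linspace(0, cands.size - 1, max_candidates).round().astype(int))
        cands = cands[idx]
        widths = widths[idx]
    return cands, widths


def estimate_threshold(all_curves, N: int | None = None) -> ThresholdHeuristic:
    """Pick the length threshold (and whisker count when unknown).

    F_n(lambda) is the set of frames with exactly n curves longer than
    lambda.  When N is given, lambda maximizes |F_N(lambda)| (ties prefer
    larger lambda).  Otherwise the pair (n, lambda) maximizes
    |F_n(lambda)| over n >= 1; ties there prefer the lambda sitting in the
    widest gap of the observed length distribution (the most separable
    threshold), then larger lambda, then larger n.
    """
    per_frame = _frame_lengths(all_curves)
    if not per_frame or all(v.size == 0 for v in per_frame):
        raise ValueError("estimate_threshold needs at least one curve")
    all_lengths = np.concatenate([v for v in per_frame if v.size])
    cands, gap_widths = candidate_thresholds(all_lengths)
    # counts[t, c] = number of curves in frame t longer than candidate c
    counts = np.stack(
        [v.size - np.searchsorted(v, cands, side="right") for v in per_frame]
    )
    best = None
    max_n = int(counts.max())
    if N is not None:
        sizes = (counts == N).sum(axis=0)
        best = None  # (|F_N|, lambda)
        for ci in range(cands.size):
            key = (int(sizes[ci]), float(cands[ci]))
            if best is None or key > best:
                best = key
        size, lam, n = best[0], best[1], N
    else:
        best = None  # (|F_n|, gap width, lambda, n)
        for n in range(1, max_n + 1):
            sizes = (counts == n).sum(axis=0)
            for ci in range(cands.size):
                if sizes[ci] == 0:
                    continue
                key = (int(sizes[ci]), float(gap_widths[ci]), float(cands[ci]), n)
                if best is None or key > best:
                    best = key
        if best is not None:
            size, _, lam, n = best
    if best is None or size == 0:
        raise ValueError(
            "no (n, lambda) selects any training frame; supply N manually"
        )
    training = {
        t for t in range(len(per_frame)) if int((per_frame[t] > lam).sum()) == n
    }
    return ThresholdHeuristic(N=n, lambda_px=lam, training_frames=training)


# -- histogram models -----------------------------------------------------


class _HistogramSet:
    """Per-feature add-one-smoothed histograms for two classes (W and FP)."""

    def __init__(self, edges, logp_w, logp_fp):
        self.edges = edges  # list of (B+1,) arrays
        self.logp_w = logp_w  # (6, B)
        self.logp_fp = logp_fp

    @classmethod
    def fit(cls, samples_w: np.ndarray, samples_fp: np.ndarray, n_bins: int = N_BINS):
        """``samples_*`` are (n, 6); either class may be empty (uniform)."""
        both = [s for s in (samples_w, samples_fp) if s.size]
        allv = np.concatenate(both) if both else np.zeros((1, N_FEATURES))
        edges = []
        logp_w = np.empty((N_FEATURES, n_bins))
        logp_fp = np.empty((N_FEATURES, n_bins))
        for f in range(N_FEATURES):
            lo = float(allv[:, f].min())
            hi = float(allv[:, f].max())
            if hi <= lo:
                hi = lo + 1.0
            e = np.linspace(lo, hi, n_bins + 1)
            edges.append(e)
            for cls_samples, out in ((samples_w, logp_w), (samples_fp, logp_fp)):
                if cls_samples.size:
                    c, _ = np.histogram(cls_samples[:, f], bins=e)
                else:
                    c = np.zeros(n_bins, dtype=int)
                c = c + 1  # add-one smoothing: no zero bins
                out[f] = np.log(c / c.sum())
        return cls(edges, logp_w, logp_fp)

    def _bins(self, vec: np.ndarray) -> np.ndarray:
        idx = np.empty(N_FEATURES, dtype=int)
        for f in range(N_FEATURES):
            e = self.edges[f]
            b = int(np.searchsorted(e, vec[f], side="right")) - 1
            idx[f] = min(max(b, 0), e.size - 2)  # clamp to edge bins
        return idx

    def log_likelihood(self, vec: np.ndarray, kind: str) -> float:
        idx = self._bins(vec)
        table = self.logp_w if kind == "W" else self.logp_fp
        return float(table[np.arange(N_FEATURES), idx].sum())

    def mean_log_mass(self, kind: str) -> float:
        table = self.logp_w if kind == "W" else self.logp_fp
        return float(table.mean(axis=1).sum())


class ShapeModel(_HistogramSet):
    """P(curve | kind) as a product of per-feature histogram masses."""


class ChangeModel(_HistogramSet):
    """P(feature change | correspondence) between successive frames.

    ``missing_log_mass(kind)`` is the neutral constant used when no unique
    correspondent exists (absent whisker, or any false positive).
    """

    def missing_log_mass(self, kind: str) -> float:
        return self.mean_log_mass(kind)


# -- label chain ----------------------------------------------------------


def label_name(state: int) -> str:
    """State index -> label string.  Even states are F_i, odd are W_{i+1}."""
    return f"F{state // 2}" if state % 2 == 0 else f"W{(state + 1) // 2}"


def state_of_label(label: str) -> int:
    i = int(label[1:])
    return 2 * i if label[0] == "F" else 2 * i - 1


def n_states(n_whiskers: int) -> int:
    return 2 * n_whiskers + 1


def is_w(state: int) -> bool:
    return state % 2 == 1


def transition_legal(s_from: int, s_to: int) -> bool:
    """Ordering rules: labels are non-decreasing along the chain and each
    W_i appears at most once."""
    if s_to > s_from:
        return True
    return s_to == s_from and not is_w(s_from)


class TransitionModel:
    """Smoothed start/pairwise label frequencies on the ordered chain."""

    def __init__(self, n_whiskers: int):
        self.N = n_whiskers
        S = n_states(n_whiskers)
        self.start_counts = np.zeros(S)
        self.pair_counts = np.zeros((S, S))
        self.n_empty = 0
        self.n_frames = 0
        self._log_start = None
        self._log_pair = None

    def observe(self, states) -> None:
        self.n_frames += 1
        if not states:
            self.n_empty += 1
            return
        self.start_counts[states[0]] += 1
        for a, b in zip(states[:-1], states[1:]):
            if not transition_legal(a, b):
                raise ValueError(f"illegal training transition {a}->{b}")
            self.pair_counts[a, b] += 1
        self._log_start = None
        self._log_pair = None

    def _finalize(self):
        S = n_states(self.N)
        start = self.start_counts + 1.0
        self._log_start = np.log(start / start.sum())
        pair = np.full((S, S), -np.inf)
        for a in range(S):
            legal = np.array([transition_legal(a, b) for b in range(S)])
            row = self.pair_counts[a, legal] + 1.0
            pair[a, legal] = np.log(row / row.sum())
        self._log_pair = pair

    @property
    def log_start(self) -> np.ndarray:
        if self._log_start is None:
            self._finalize()
        return self._log_start

    @property
    def log_pair(self) -> np.ndarray:
        if self._log_pair is None:
            self._finalize()
        return self._log_pair

    @property
    def log_empty(self) -> float:
        return math.log((self.n_empty + 1.0) / (self.n_frames + 2.0))


@dataclass
class FrameLabeling:
    """Labels for one frame's curves, in anterior-posterior curve order."""

    frame_index: int
    labels: list  # label strings, one per curve (AP-sorted order)
    log_score: float

    @property
    def states(self):
        return [state_of_label(l) for l in self.labels]


def assert_valid_labeling(labels, n_whiskers: int) -> None:
    """Structural check of the ordering and uniqueness rules."""
    states = [state_of_label(l) for l in labels]
    for a, b in zip(states[:-1], states[1:]):
        if not transition_legal(a, b):
            raise AssertionError(f"illegal label order {label_name(a)}->{label_name(b)}")
    w = [s for s in states if is_w(s)]
    if len(w) != len(set(w)):
        raise AssertionError("duplicate whisker label")


@dataclass
class LinkModel:
    """Everything learned from one video."""

    heuristic: ThresholdHeuristic
    shape: ShapeModel
    transitions: TransitionModel
    change: ChangeModel | None = None


def label_frame(
    features,
    shape_model: ShapeModel,
    transition_model: TransitionModel,
    change_model: ChangeModel | None = None,
    neighbor=None,
    frame_index: int = 0,
) -> FrameLabeling:
    """Exact Viterbi labeling of one frame's AP-ordered curves.

    ``neighbor`` is an optional (FrameLabeling, features_list) pair from an
    adjacent frame; with a change model it contributes the correspondence
    likelihood: W_i terms compare against the neighbor's W_i curve (or pay
    the missing-correspondence constant), F terms use a constant because
    false positives have no unique correspondent.
    """
    M = len(features)
    S = n_states(transition_model.N)
    if M == 0:
        return FrameLabeling(frame_index, [], transition_model.log_empty)

    vecs = [f.vector() for f in features]
    neighbor_w = {}
    if neighbor is not None:
        nb_labeling, nb_features = neighbor
        for lbl, f in zip(nb_labeling.labels, nb_features):
            if lbl.startswith("W"):
                neighbor_w[state_of_label(lbl)] = f.vector()

    def emission(ci: int, s: int) -> float:
        kind = "W" if is_w(s) else "FP"
        e = shape_model.log_likelihood(vecs[ci], kind)
        if change_model is not None and neighbor is not None:
            if is_w(s):
                ref = neighbor_w.get(s)
                if ref is not None:
                    e += change_model.log_likelihood(vecs[ci] - ref, "W")
                else:
                    e += change_model.missing_log_mass("W")
            else:
                e += change_model.missing_log_mass("FP")
        return e

    em = np.array([[emission(ci, s) for s in range(S)] for ci in range(M)])
    log_start = transition_model.log_start
    log_pair = transition_model.log_pair

    dp = log_start + em[0]
    back = np.zeros((M, S), dtype=int)
    for ci in range(1, M):
        cand = dp[:, None] + log_pair  # (from, to)
        back[ci] = np.argmax(cand, axis=0)
        dp = cand[back[ci], np.arange(S)] + em[ci]
    s = int(np.argmax(dp))
    total = float(dp[s])
    states = [s]
    for ci in range(M - 1, 0, -1):
        s = int(back[ci, s])
        states.append(s)
    states.reverse()
    labels = [label_name(s) for s in states]
    assert_valid_labeling(labels, transition_model.N)
    return FrameLabeling(frame_index, labels, total / M)


# -- whole-video driver ---------------------------------------------------


def heuristic_states(features, lambda_px: float, n_whiskers: int):
    """Initial label states for one training frame: the long curves become
    W_1..W_N in AP order, everything else F_i by position."""
    states = []
    w_seen = 0
    for f in features:
        if f.length_px > lambda_px:
            w_seen += 1
            states.append(2 * w_seen - 1)
        else:
            states.append(2 * w_seen)
    if w_seen != n_whiskers:
        raise ValueError("frame is not a valid training frame")
    return states


def _match_changes(labeling_a, feats_a, labeling_b, feats_b):
    """Feature-change samples between two adjacent labeled frames.

    W_i matches its counterpart directly; F curves with the same label are
    zipped in AP order.
    """
    dw, dfp = [], []
    by_label_a, by_label_b = {}, {}
    for lbl, f in zip(labeling_a.labels, feats_a):
        by_label_a.setdefault(lbl, []).append(f)
    for lbl, f in zip(labeling_b.labels, feats_b):
        by_label_b.setdefault(lbl, []).append(f)
    for lbl, fa in by_label_a.items():
        fb = by_label_b.get(lbl)
        if not fb:
            continue
        pairs = zip(fa, fb)
        target = dw if lbl.startswith("W") else dfp
        for a, b in pairs:
            target.append(b.vector() - a.vector())
    return dw, dfp


def build_models(frame_features, heuristic: ThresholdHeuristic) -> LinkModel:
    """Shape + transition models from the heuristically labeled training set."""
    shape_w, shape_fp = [], []
    trans = TransitionModel(heuristic.N)
    for t in sorted(heuristic.training_frames):
        feats = frame_features[t]
        states = heuristic_states(feats, heuristic.lambda_px, heuristic.N)
        trans.observe(states)
        for f, s in zip(feats, states):
            (shape_w if is_w(s) else shape_fp).append(f.vector())
    if not shape_fp:
        log.info("no false-positive curves in training; FP histograms uniform")
    shape = ShapeModel.fit(
        np.array(shape_w) if shape_w else np.empty((0, N_FEATURES)),
        np.array(shape_fp) if shape_fp else np.empty((0, N_FEATURES)),
    )
    return LinkModel(heuristic=heuristic, shape=shape, transitions=trans)


def link_video(all_curves, face: FaceConfig, N: int | None = None):
    """Label every frame of a video.

    ``all_curves``: per-frame lists of TracedCurve.  Returns
    (labelings, model, order) where ``labelings[t].labels`` aligns with
    frame t's curves sorted in AP order and ``order[t]`` maps the sorted
    position back to the index in the input list.
    """
    T = len(all_curves)
    if T == 0:
        raise ValueError("link_video needs at least one frame")

    frame_features = []
    order = []
    for curves in all_curves:
        feats = [compute_features(c, face) for c in curves]
        idx = sorted(
            range(len(feats)), key=lambda i: (feats[i].endpoint_follicle, i)
        )
        order.append(idx)
        frame_features.append([feats[i] for i in idx])

    heuristic = estimate_threshold(
        [[f.length_px for f in feats] for feats in frame_features], N
    )
    model = build_models(frame_features, heuristic)

    # preliminary shape-only labeling of every frame
    shape_only = [
        label_frame(
            frame_features[t], model.shape, model.transitions, frame_index=t
        )
        for t in range(T)
    ]

    # change histograms from adjacent shape-labeled training frames
    dw, dfp = [], []
    for t in sorted(heuristic.training_frames):
        if t + 1 in heuristic.training_frames:
            a, b = _match_changes(
                shape_only[t],
                frame_features[t],
                shape_only[t + 1],
                frame_features[t + 1],
            )
            dw.extend(a)
            dfp.extend(b)
    model.change = ChangeModel.fit(
        np.array(dw) if dw else np.empty((0, N_FEATURES)),
        np.array(dfp) if dfp else np.empty((0, N_FEATURES)),
    )

    if T == 1:
        return shape_only, model, order

    # Confidence-ordered propagation: visit frames best-first, letting each
    # visited frame relabel its unvisited neighbors under the full model.
    # Confidence tiers keep ambiguous frames from seeding label waves:
    # heuristic training frames (exactly N long curves — unambiguous) go
    # first, then frames already conditioned by a visited neighbor; a frame
    # that nothing has vouched for yet is visited only as a last resort.
    labelings = list(shape_only)
    visited = [False] * T
    version = [0] * T
    training = model.heuristic.training_frames
    heap = [
        ((0 if t in training else 2), -labelings[t].log_score, t, 0)
        for t in range(T)
    ]
    heapq.heapify(heap)
    n_visited = 0
    while heap and n_visited < T:
        _, neg, t, ver = heapq.heappop(heap)
        if visited[t] or ver != version[t]:
            continue
        visited[t] = True
        n_visited += 1
        for nb in (t - 1, t + 1):
            if 0 <= nb < T and not visited[nb]:
                new = label_frame(
                    frame_features[nb],
                    model.shape,
                    model.transitions,
                    model.change,
                    neighbor=(labelings[t], frame_features[t]),
                    frame_index=nb,
                )
                labelings[nb] = new
                version[nb] += 1
                tier = 0 if nb in training else 1
                heapq.heappush(heap, (tier, -new.log_score, nb, version[nb]))
    return labelings, model, order
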