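"""Kinematic measurement of identified curves.

Angle at base and overall shape come from a degree-5 parametric polynomial
fit; curvature at the interest point comes from a degree-2 re-fit restricted
to a short arc window so shape outside the window cannot bias it.  The
follicle is found by linear extrapolation into the face mask, and
whisker-pole contact as the closest point to the pole center on the curve or
on a line extrapolated from its nearest end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import FaceSpec


@dataclass
class ParametricPolynomial:
    """x(t), y(t) polynomials on t in [0, 1], t = normalized arc length."""

    coeffs_x: np.ndarray  # a_0 ... a_d (ascending powers)
    coeffs_y: np.ndarray
    residual_rms: float = 0.0

    @property
    def degree(self) -> int:
        return len(self.coeffs_x) - 1

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        return (
            np.polynomial.polynomial.polyval(t, self.coeffs_x),
            np.polynomial.polynomial.polyval(t, self.coeffs_y),
        )

    def derivatives(self, t):
        t = np.asarray(t, dtype=np.float64)
        dx = np.polynomial.polynomial.polyder(self.coeffs_x)
        dy = np.polynomial.polynomial.polyder(self.coeffs_y)
        ddx = np.polynomial.polynomial.polyder(dx)
        ddy = np.polynomial.polynomial.polyder(dy)
        pv = np.polynomial.polynomial.polyval
        return pv(t, dx), pv(t, dy), pv(t, ddx), pv(t, ddy)


@dataclass
class FaceConfig:
    """Face mask geometry plus measurement parameters.

    The mask is either a half-plane bounded at an image edge or a circle;
    see :class:`whiskertrack.config.FaceSpec` for the geometry fields.
    """

    face: FaceSpec = field(default_factory=FaceSpec)
    follicle_extrapolation_px: float = 10.0
    interest_point_arc_mm: float = 5.0
    window_mm: float = 2.0

    def __post_init__(self):
        if isinstance(self.face, dict):
            self.face = FaceSpec(**self.face)
        if not (1.0 <= self.window_mm <= 2.5):
            raise ValueError("window_mm must be in [1, 2.5]")
        if self.face.side != "circle" and self.face.boundary_px is None:
            raise ValueError("face.boundary_px must be set for edge masks")

    # -- geometry --------------------------------------------------------

    def face_distance(self, points) -> np.ndarray:
        """Signed distance from the face mask boundary; positive outside the
        face (on the whisker side)."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        f = self.face
        if f.side == "left":
            d = p[:, 0] - f.boundary_px
        elif f.side == "right":
            d = f.boundary_px - p[:, 0]
        elif f.side == "top":
            d = p[:, 1] - f.boundary_px
        elif f.side == "bottom":
            d = f.boundary_px - p[:, 1]
        else:  # circle: face inside the circle
            c = np.asarray(f.circle_center, dtype=np.float64)
            d = np.linalg.norm(p - c, axis=1) - f.circle_radius
        return d if np.asarray(points).ndim == 2 else d[0]

    def lateral_unit(self, point=None) -> np.ndarray:
        """Unit vector pointing away from the face (the 0-degree axis)."""
        f = self.face
        if f.side == "left":
            return np.array([1.0, 0.0])
        if f.side == "right":
            return np.array([-1.0, 0.0])
        if f.side == "top":
            return np.array([0.0, 1.0])
        if f.side == "bottom":
            return np.array([0.0, -1.0])
        c = np.asarray(f.circle_center, dtype=np.float64)
        v = np.asarray(point, dtype=np.float64) - c
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([1.0, 0.0])

    def anterior_unit(self, point=None) -> np.ndarray:
        """Unit vector along the face edge toward increasing whisker index
        (protraction-positive)."""
        lat = self.lateral_unit(point)
        ant = np.array([-lat[1], lat[0]])
        if not self.face.anterior_positive:
            ant = -ant
        return ant

    def ap_position(self, points):
        """Scalar anterior-posterior coordinate (px) of point(s)."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        f = self.face
        if f.side == "circle":
            c = np.asarray(f.circle_center, dtype=np.float64)
            v = p - c
            ang = np.arctan2(v[:, 1], v[:, 0])
            out = ang * f.circle_radius
            if not f.anterior_positive:
                out = -out
        else:
            out = p @ self.anterior_unit()
        return out if np.asarray(points).ndim == 2 else out[0]

    def angle_from_tangent(self, tangent, point=None) -> float:
        """Angle in degrees: 0 on the lateral axis, protraction positive."""
        lat = self.lateral_unit(point)
        ant = self.anterior_unit(point)
        t = np.asarray(tangent, dtype=np.float64)
        return math.degrees(math.atan2(float(t @ ant), float(t @ lat)))


@dataclass
class WhiskerRecord:
    """Measured features of one identified whisker in one frame."""

    frame: int
    label: str
    length_px: float
    angle_at_base_deg: float
    curvature_per_mm: float | None
    follicle: tuple
    tip: tuple
    mean_score: float
    contact_point: tuple | None = None
    contact_distance_px: float | None = None


def arc_length_param(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length normalized to [0, 1]."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline (zero length)")
    return s / total


def fit_parametric(points, degree: int) -> ParametricPolynomial:
    """Least-squares parametric polynomial fit with arc-length parameter.

    x(t) and y(t) are fit independently.  On rank deficiency (or too few
    points) the degree is reduced until the fit is well posed.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    t = arc_length_param(pts)
    d = int(degree)
    while d > 1 and pts.shape[0] < d + 1:
        d -= 1
    while True:
        V = np.vander(t, d + 1, increasing=True)
        cx, _, rank, _ = np.linalg.lstsq(V, pts[:, 0], rcond=None)
        cy = np.linalg.lstsq(V, pts[:, 1], rcond=None)[0]
        if rank == d + 1 or d == 1:
            break
        d -= 1
    fx = np.polynomial.polynomial.polyval(t, cx)
    fy = np.polynomial.polynomial.polyval(t, cy)
    rms = float(np.sqrt(np.mean((fx - pts[:, 0]) ** 2 + (fy - pts[:, 1]) ** 2)))
    return ParametricPolynomial(cx, cy, rms)


def curvature_at(poly: ParametricPolynomial, t) -> float:
    """Signed curvature kappa(t) = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2).

    Positive when the curve bends counterclockwise in (x, y) coordinates
    (toward the left of the travel direction).
    """
    dx, dy, ddx, ddy = poly.derivatives(t)
    speed2 = dx * dx + dy * dy
    if np.any(speed2 < 1e-12):
        raise ValueError("degenerate parameterization (vanishing speed)")
    return (dx * ddy - dy * ddx) / speed2**1.5


def _orient_to_face(points: np.ndarray, face: FaceConfig) -> np.ndarray:
    """Order points so index 0 is the face-side end."""
    d0 = face.face_distance(points[0])
    d1 = face.face_distance(points[-1])
    return points[::-1].copy() if d1 < d0 else points


def _reference_on_polyline(points: np.ndarray, face: FaceConfig):
    """(reference point, its signed arc position along the polyline).

    The reference is where the polyline crosses the face-mask boundary, or a
    linear extrapolation of the face-side end onto it (negative arc
    position).
    """
    d = face.face_distance(points)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    inside = d <= 0.0
    if inside.any():
        if inside.all():
            raise ValueError("curve lies entirely inside the face mask")
        k = int(np.nonzero(~inside)[0][0])  # first point outside the face
        if k == 0:
            k = int(np.nonzero(inside)[0][0])
            a, b = k - 1, k
        else:
            a, b = k - 1, k
        f = d[a] / (d[a] - d[b])
        ref = points[a] + f * (points[b] - points[a])
        return ref, float(s[a] + f * (s[b] - s[a]))
    # extrapolate backwards from the face-side end
    tan = points[1] - points[0]
    n = np.linalg.norm(tan)
    if n == 0:
        raise ValueError("degenerate curve start")
    tan = tan / n
    # signed distance decreases fastest along -tan if tan points away
    rate = float(
        face.face_distance(points[0] - 1e-3 * tan) - d[0]
    ) / -1e-3
    if rate <= 1e-9:
        raise ValueError("cannot extrapolate curve onto the face mask")
    back = d[0] / rate
    ref = points[0] - back * tan
    return ref, float(-back)


def measure_whisker(
    curve,
    face: FaceConfig,
    pixel_size_um: float,
    pole=None,
    label: str = "W1",
    frame_index: int | None = None,
    scores: np.ndarray | None = None,
) -> WhiskerRecord:
    """Full kinematic measurement of one identified curve.

    ``curve`` may be a TracedCurve or an (N, 2) point array.  ``pole`` is an
    optional ((x, y), radius) tuple.
    """
    if hasattr(curve, "points"):
        pts = curve.points
        scores = curve.scores if scores is None else scores
        if frame_index is None:
            frame_index = curve.frame_index
    else:
        pts = np.asarray(curve, dtype=np.float64)
    if frame_index is None:
        frame_index = 0
    if pts.shape[0] < 6:
        raise ValueError("measure_whisker needs at least 6 points")

    pts = _orient_to_face(pts, face)
    px_per_mm = 1000.0 / pixel_size_um

    poly5 = fit_parametric(pts, 5)
    ref, s_ref = _reference_on_polyline(pts, face)

    # angle at base: tangent of the degree-5 fit at the reference arc position
    total = arc_length_param(pts)  # validates length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_total = float(seg.sum())
    t_ref = min(max(s_ref / s_total, 0.0), 1.0)
    dx, dy, _, _ = poly5.derivatives(t_ref)
    angle = face.angle_from_tangent((float(dx), float(dy)), ref)

    # windowed curvature at the interest point
    s_interest = s_ref + face.interest_point_arc_mm * px_per_mm
    half_win = 0.5 * face.window_mm * px_per_mm
    curvature = _windowed_curvature(pts, s_interest, half_win, px_per_mm)

    # follicle: linear extrapolation into the face from the reference point
    tan0 = np.array([float(dx), float(dy)])
    n0 = np.linalg.norm(tan0)
    tan0 = tan0 / n0 if n0 > 0 else np.array([1.0, 0.0])
    if float(face.face_distance(ref + tan0) - face.face_distance(ref)) < 0:
        tan0 = -tan0  # ensure tan0 points away from the face
    follicle = ref - face.follicle_extrapolation_px * tan0

    record = WhiskerRecord(
        frame=int(frame_index),
        label=label,
        length_px=s_total,
        angle_at_base_deg=float(angle),
        curvature_per_mm=curvature,
        follicle=(float(follicle[0]), float(follicle[1])),
        tip=(float(pts[-1, 0]), float(pts[-1, 1])),
        mean_score=float(np.mean(scores)) if scores is not None else 0.0,
    )
    if pole is not None:
        center, radius = np.asarray(pole[0], dtype=np.float64), float(pole[1])
        cp, cd = _contact_point(poly5, center)
        record.contact_point = (float(cp[0]), float(cp[1]))
        record.contact_distance_px = float(cd)
    return record


def _windowed_curvature(pts, s_interest, half_win, px_per_mm):
    """Degree-2 re-fit over the arc window around the interest point.

    Returns curvature in 1/mm, or None when the interest point lies beyond
    the curve and outside the window.
    """
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    lo, hi = s_interest - half_win, s_interest + half_win
    sel = (s >= lo) & (s <= hi)
    if sel.sum() < 3 or s_interest < -half_win or s_interest > s[-1] + half_win:
        return None
    window = pts[sel]
    sw = s[sel]
    poly2 = fit_parametric(window, 2)
    span = sw[-1] - sw[0]
    if span <= 0:
        return None
    t_star = min(max((s_interest - sw[0]) / span, 0.0), 1.0)
    kappa_px = float(curvature_at(poly2, t_star))
    return kappa_px * px_per_mm


def _contact_point(poly: ParametricPolynomial, center, n_samples: int = 1024):
    """Closest point to the pole center on the fitted curve or on a tangent
    line extrapolated from its nearest end."""
    t = np.linspace(0.0, 1.0, n_samples)
    x, y = poly(t)
    pts = np.stack([x, y], axis=1)
    d = np.linalg.norm(pts - center, axis=1)
    k = int(np.argmin(d))
    best_p, best_d = pts[k], float(d[k])
    if k in (0, n_samples - 1):
        t_end = 0.0 if k == 0 else 1.0
        dx, dy, _, _ = poly.derivatives(t_end)
        tan = np.array([float(dx), float(dy)])
        n = np.linalg.norm(tan)
        if n > 0:
            tan /= n
            if k == 0:
                tan = -tan  # extrapolate beyond the start
            end = pts[k]
            proj = float((np.asarray(center) - end) @ tan)
            if proj > 0:
                q = end + proj * tan
                dq = float(np.linalg.norm(q - center))
                if dq < best_d:
                    best_p, best_d = q, dq
    return best_p, best_d


def contact_episodes(records, pole, curvature_change_threshold: float = 0.0, margin_px: float = 2.0):
    """Contact episodes from a whisker's time series of records.

    Episodes are maximal runs of frames with contact distance within
    pole radius + margin; the resting curvature is the median over
    non-contact frames.  Returns a list of (start_frame, end_frame,
    peak_delta_kappa).
    """
    recs = sorted(records, key=lambda r: r.frame)
    radius = float(pole[1])
    thresh = radius + margin_px
    in_contact = np.array(
        [r.contact_distance_px is not None and r.contact_distance_px <= thresh for r in recs]
    )
    rest = [
        r.curvature_per_mm
        for r, c in zip(recs, in_contact)
        if not c and r.curvature_per_mm is not None
    ]
    if not rest:
        raise ValueError("no non-contact frames: resting curvature undefined")
    kappa_rest = float(np.median(rest))
    episodes = []
    i = 0
    n = len(recs)
    while i < n:
        if in_contact[i]:
            j = i
            while j + 1 < n and in_contact[j + 1]:
                j += 1
            deltas = [
                abs(r.curvature_per_mm - kappa_rest)
                for r in recs[i : j + 1]
                if r.curvature_per_mm is not None
            ]
            peak = max(deltas) if deltas else 0.0
            if peak >= curvature_change_threshold:
                episodes.append((recs[i].frame, recs[j].frame, peak))
            i = j + 1
        else:
            i += 1
    return episodes
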