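"""Ground-truthed synthetic whisker videos.

Scenes emulate silhouette imaging of a single whisker row: dark tapered
curves anchored at a face edge whisking over a bright background, short
distractor hairs, an occluding pole disk, sensor noise and the odd-line
intensity artifact.  Whisker backbones are quadratic Beziers in a
face-anchored frame, so tangents and curvature are closed-form and every
rendered frame carries exact analytic ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import FaceSpec
from .imgproc import Frame


@dataclass
class WhiskerSpec:
    """One whisker: geometry plus its angular motion model.

    ``base_pos`` is the anterior-posterior coordinate of the base along the
    face edge; the base sits ``base_depth_px`` beyond the edge (inside the
    face) so only the shaft is imaged.  Deflection angles are measured from
    the lateral axis, protraction positive.
    """

    base_pos: float
    length_px: float = 150.0
    base_width_px: float = 2.8
    tip_width_px: float = 0.7
    curl_px: float = 10.0  # perpendicular offset of the far control point
    rest_deflection_deg: float = 15.0
    whisk_amplitude_deg: float = 12.0
    phase_rad: float = 0.0
    base_depth_px: float = 2.0


@dataclass
class HairSpec:
    """Short static distractor hair anchored at the face edge."""

    base_pos: float
    length_px: float = 30.0
    width_px: float = 1.2
    deflection_deg: float = 0.0
    curl_px: float = 2.0
    base_depth_px: float = 1.0


@dataclass
class SceneSpec:
    """Full description of a synthetic video."""

    width: int = 256
    height: int = 180
    face_side: str = "bottom"
    anterior_positive: bool = True
    whiskers: list = field(default_factory=list)
    hairs: list = field(default_factory=list)
    pole: tuple | None = None  # (x, y, radius)
    pole_intensity: float = 30.0
    background: float = 200.0
    core_intensity: float = 40.0
    illum_gradient: float = 0.0  # relative left-right background slope
    noise_sigma: float = 0.0
    line_bias_gain: float = 1.0  # odd rows multiplied by this (1 = off)
    profile: str = "rect"  # cross-section model: "rect" or "gauss"
    whisk_freq_per_frame: float = 0.011
    fps: float = 1000.0
    seed: int = 0
    visible_min_arc_px: float = 80.0
    # transient: dict(start, whisker, offsets_deg)
    transient: dict | None = None
    # exit episode: dict(start, duration, whisker, deflection_deg)
    exit_episode: dict | None = None

    def __post_init__(self):
        self.whiskers = [
            WhiskerSpec(**w) if isinstance(w, dict) else w for w in self.whiskers
        ]
        self.hairs = [HairSpec(**h) if isinstance(h, dict) else h for h in self.hairs]
        if self.profile not in ("rect", "gauss"):
            raise ValueError("profile must be 'rect' or 'gauss'")

    @property
    def n_whiskers(self) -> int:
        return len(self.whiskers)

    def face_spec(self, boundary_margin: float = 2.0) -> FaceSpec:
        if self.face_side == "bottom":
            b = self.height - 1 - boundary_margin
        elif self.face_side == "top":
            b = boundary_margin
        elif self.face_side == "left":
            b = boundary_margin
        else:
            b = self.width - 1 - boundary_margin
        return FaceSpec(
            side=self.face_side,
            boundary_px=b,
            anterior_positive=self.anterior_positive,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "pole" in d and d["pole"] is not None:
            d["pole"] = tuple(d["pole"])
        return cls(**d)


# -- geometry -------------------------------------------------------------


def _face_units(side: str, anterior_positive: bool):
    lat = {
        "bottom": np.array([0.0, -1.0]),
        "top": np.array([0.0, 1.0]),
        "left": np.array([1.0, 0.0]),
        "right": np.array([-1.0, 0.0]),
    }[side]
    ant = np.array([-lat[1], lat[0]])
    if not anterior_positive:
        ant = -ant
    return lat, ant


def _base_point(scene: SceneSpec, base_pos: float, depth: float) -> np.ndarray:
    lat, ant = _face_units(scene.face_side, scene.anterior_positive)
    if scene.face_side == "bottom":
        edge = np.array([0.0, scene.height - 1.0])
    elif scene.face_side == "top":
        edge = np.array([0.0, 0.0])
    elif scene.face_side == "left":
        edge = np.array([0.0, 0.0])
    else:
        edge = np.array([scene.width - 1.0, 0.0])
    # point on the edge at AP coordinate base_pos, pushed into the face
    p = edge + ant * 0.0
    if scene.face_side in ("bottom", "top"):
        p = np.array([base_pos if scene.anterior_positive else -base_pos, edge[1]])
    else:
        p = np.array([edge[0], base_pos if scene.anterior_positive else -base_pos])
    return p - lat * depth


def bezier_control_points(scene: SceneSpec, w, deflection_deg: float):
    """Control points of the quadratic Bezier backbone at a deflection."""
    lat, ant = _face_units(scene.face_side, scene.anterior_positive)
    th = math.radians(deflection_deg)
    d = lat * math.cos(th) + ant * math.sin(th)
    nvec = np.array([-d[1], d[0]])
    p0 = _base_point(scene, w.base_pos, w.base_depth_px)
    p1 = p0 + 0.5 * w.length_px * d
    p2 = p0 + w.length_px * d + w.curl_px * nvec
    return p0, p1, p2


def bezier_eval(p0, p1, p2, t):
    t = np.asarray(t, dtype=np.float64)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def sample_backbone(scene: SceneSpec, obj, deflection_deg: float, ds: float = 0.2):
    """(points, widths) sampled at roughly ``ds`` px arc spacing."""
    p0, p1, p2 = bezier_control_points(scene, obj, deflection_deg)
    n = max(int(obj.length_px / ds), 16)
    t = np.linspace(0.0, 1.0, n)
    pts = bezier_eval(p0, p1, p2, t)
    if hasattr(obj, "base_width_px"):
        widths = obj.base_width_px + (obj.tip_width_px - obj.base_width_px) * t
    else:
        widths = np.full(n, obj.width_px)
    return pts, widths


def deflection_at(scene: SceneSpec, wi: int, frame_index: int) -> float:
    w = scene.whiskers[wi]
    d = w.rest_deflection_deg + w.whisk_amplitude_deg * math.sin(
        2 * math.pi * scene.whisk_freq_per_frame * frame_index + w.phase_rad
    )
    tr = scene.transient
    if tr and wi == tr["whisker"]:
        j = frame_index - tr["start"]
        if 0 <= j < len(tr["offsets_deg"]):
            d += tr["offsets_deg"][j]
    ex = scene.exit_episode
    if ex and wi == ex["whisker"]:
        if ex["start"] <= frame_index < ex["start"] + ex["duration"]:
            d = ex["deflection_deg"]
    return d


# -- rendering ------------------------------------------------------------


def _stamp_curve(canvas, pts, widths, core, profile):
    """Darken the canvas along a sampled backbone.

    ``rect``: exact 1-D pixel-box anti-aliasing of a rectangular valley of
    the local width (matches the tracer's valley model).  ``gauss``: Gaussian
    cross-section with sigma = width/2.
    """
    h, w = canvas.shape
    pad = widths.max() / 2.0 + 1.5
    x0 = max(int(math.floor(pts[:, 0].min() - pad)), 0)
    x1 = min(int(math.ceil(pts[:, 0].max() + pad)), w - 1)
    y0 = max(int(math.floor(pts[:, 1].min() - pad)), 0)
    y1 = min(int(math.ceil(pts[:, 1].max() + pad)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float64)
    tree = cKDTree(pts)
    dist, idx = tree.query(grid, k=1)
    wd = widths[idx]
    if profile == "rect":
        ov = np.minimum(wd / 2.0, dist + 0.5) - np.maximum(-wd / 2.0, dist - 0.5)
        cov = np.clip(ov, 0.0, 1.0)
    else:
        sigma = np.maximum(wd / 2.0, 1e-6)
        cov = np.exp(-0.5 * (dist / sigma) ** 2)
    region = canvas[y0 : y1 + 1, x0 : x1 + 1]
    region -= (cov.reshape(region.shape)) * (region - core)


def _stamp_disk(canvas, center, radius, intensity):
    h, w = canvas.shape
    x0 = max(int(math.floor(center[0] - radius - 1)), 0)
    x1 = min(int(math.ceil(center[0] + radius + 1)), w - 1)
    y0 = max(int(math.floor(center[1] - radius - 1)), 0)
    y1 = min(int(math.ceil(center[1] + radius + 1)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    gy, gx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    d = np.hypot(gx - center[0], gy - center[1])
    cov = np.clip(radius + 0.5 - d, 0.0, 1.0)
    region = canvas[y0 : y1 + 1, x0 : x1 + 1]
    region -= cov * (region - intensity)


def _visible_truth(scene: SceneSpec, pts: np.ndarray):
    """Clip a backbone to the image; returns (points, arc_len)."""
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= scene.width - 1)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= scene.height - 1)
    )
    vis = pts[inside]
    if vis.shape[0] < 2:
        return vis, 0.0
    arc = float(np.linalg.norm(np.diff(vis, axis=0), axis=1).sum())
    return vis, arc


def render_frame(scene: SceneSpec, frame_index: int, pixel_size_um: float = 17.5):
    """Render one frame; returns (Frame, truth).

    ``truth`` maps 'whiskers' to a list (one entry per whisker, in
    anterior-posterior base order) of dicts with the clipped analytic
    backbone ('points', sampled at 0.5 px), 'visible', 'arc_len_px' and
    'deflection_deg'.  Intensities are quantized to integers exactly as the
    TIFF writer stores them, so in-memory and on-disk pipelines agree.
    """
    h, w = scene.height, scene.width
    x_rel = np.linspace(-0.5, 0.5, w)[None, :]
    canvas = np.full((h, w), scene.background, dtype=np.float64)
    canvas *= 1.0 + scene.illum_gradient * x_rel

    truth_whiskers = []
    for wi, wsp in enumerate(scene.whiskers):
        d = deflection_at(scene, wi, frame_index)
        pts, widths = sample_backbone(scene, wsp, d)
        _stamp_curve(canvas, pts, widths, scene.core_intensity, scene.profile)
        tpts, twid = sample_backbone(scene, wsp, d, ds=0.5)
        vis, arc = _visible_truth(scene, tpts)
        truth_whiskers.append(
            {
                "points": vis,
                "visible": bool(arc >= scene.visible_min_arc_px),
                "arc_len_px": arc,
                "deflection_deg": float(d),
            }
        )
    for hsp in scene.hairs:
        pts, widths = sample_backbone(scene, hsp, hsp.deflection_deg)
        _stamp_curve(canvas, pts, widths, scene.core_intensity, scene.profile)
    if scene.pole is not None:
        _stamp_disk(
            canvas,
            (scene.pole[0], scene.pole[1]),
            scene.pole[2],
            scene.pole_intensity,
        )

    if scene.line_bias_gain != 1.0:
        canvas[1::2] *= scene.line_bias_gain
    if scene.noise_sigma > 0:
        rng = np.random.default_rng([scene.seed, frame_index])
        canvas = canvas + rng.normal(0.0, scene.noise_sigma, canvas.shape)
    canvas = np.rint(np.clip(canvas, 0.0, 255.0))

    frame = Frame(canvas, frame_index, pixel_size_um)
    return frame, {"whiskers": truth_whiskers}


def iter_frames(scene: SceneSpec, n_frames: int, pixel_size_um: float = 17.5):
    for t in range(n_frames):
        yield render_frame(scene, t, pixel_size_um)


def make_benchmark(scene: SceneSpec, n_frames: int, out_dir=None, pixel_size_um: float = 17.5):
    """Render a full video plus its truth bundle.

    Returns (frames, truths).  With ``out_dir`` set, also writes
    video.tif (uint8 multi-page), truth.json and scene.json there.
    """
    frames, truths = [], []
    for t in range(n_frames):
        fr, tr = render_frame(scene, t, pixel_size_um)
        frames.append(fr)
        truths.append(tr)
    if out_dir is not None:
        import os

        from . import io as wio

        os.makedirs(out_dir, exist_ok=True)
        wio.write_video_tiff(os.path.join(out_dir, "video.tif"), frames)
        wio.write_truth(os.path.join(out_dir, "truth.json"), scene, truths)
        with open(os.path.join(out_dir, "scene.json"), "w") as fh:
            json.dump(scene.to_dict(), fh, indent=2)
            fh.write("\n")
    return frames, truths


# -- stock scenes ---------------------------------------------------------


def default_scene(seed: int = 0, noise_sigma: float = 1.0, **overrides) -> SceneSpec:
    """The default 4-whisker row with 6 distractor hairs."""
    whiskers = [
        WhiskerSpec(base_pos=40.0, length_px=149.0, base_width_px=3.2, curl_px=10.0,
                    rest_deflection_deg=14.0),
        WhiskerSpec(base_pos=70.0, length_px=151.0, base_width_px=2.8, curl_px=8.0,
                    rest_deflection_deg=15.0),
        WhiskerSpec(base_pos=100.0, length_px=150.0, base_width_px=2.4, curl_px=11.0,
                    rest_deflection_deg=16.0),
        WhiskerSpec(base_pos=130.0, length_px=148.0, base_width_px=2.0, curl_px=9.0,
                    rest_deflection_deg=17.0),
    ]
    # hairs flank the whisker row (posterior of the first whisker's sweep,
    # anterior of the last whisker's reach) so they stay clear of the
    # whiskers through the whole whisk cycle; each is long enough to cross
    # the 50-px seeding grid
    hairs = [
        HairSpec(base_pos=6.0, length_px=40.0, width_px=1.2, deflection_deg=18.0),
        HairSpec(base_pos=17.0, length_px=44.0, width_px=1.1, deflection_deg=24.0),
        HairSpec(base_pos=26.0, length_px=38.0, width_px=1.3, deflection_deg=10.0),
        HairSpec(base_pos=185.0, length_px=42.0, width_px=1.0, deflection_deg=-16.0),
        HairSpec(base_pos=212.0, length_px=40.0, width_px=1.2, deflection_deg=-24.0),
        HairSpec(base_pos=238.0, length_px=42.0, width_px=1.1, deflection_deg=-30.0),
    ]
    spec = dict(
        width=256,
        height=180,
        whiskers=whiskers,
        hairs=hairs,
        noise_sigma=noise_sigma,
        illum_gradient=0.04,
        seed=seed,
    )
    spec.update(overrides)
    return SceneSpec(**spec)


def benchmark_scene(seed: int = 0, **overrides) -> SceneSpec:
    """The full tracking benchmark: pole, odd-line bias, one fast transient
    (>16 deg/frame at 1000 fps) and one field-exit episode on the most
    anterior whisker."""
    period = 1.0 / 0.011
    t_transient = int(round(6.75 * period))  # whisking phase near -1
    spec = default_scene(
        seed=seed,
        noise_sigma=1.5,
        pole=(125.0, 90.0, 3.0),
        line_bias_gain=0.95,
        transient={
            "start": t_transient,
            "whisker": 3,
            "offsets_deg": [17.0, 35.0, 17.0],
        },
        exit_episode={
            "start": 1200,
            "duration": 40,
            "whisker": 3,
            "deflection_deg": 88.0,
        },
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


def single_whisker_scene(
    orientation_deg: float,
    width_px: float,
    seed: int = 0,
    noise_sigma: float = 0.5,
    length_px: float = 140.0,
    curl_px: float = 6.0,
    tip_width_px: float | None = None,
) -> SceneSpec:
    """One whisker at a given backbone orientation (0 = horizontal,
    90 = vertical), used by the tracing-accuracy suite.

    Shallow orientations anchor at the left edge, steep ones at the bottom,
    so the shaft always stays clear of the image borders.
    """
    if orientation_deg <= 45.0:
        side, base, deflection = "left", 30.0, orientation_deg
    else:
        side, base, deflection = "bottom", 30.0, 90.0 - orientation_deg
    w = WhiskerSpec(
        base_pos=base,
        length_px=length_px,
        base_width_px=width_px,
        tip_width_px=width_px if tip_width_px is None else tip_width_px,
        curl_px=curl_px,
        rest_deflection_deg=deflection,
        whisk_amplitude_deg=0.0,
    )
    return SceneSpec(
        width=200,
        height=200,
        face_side=side,
        whiskers=[w],
        hairs=[],
        noise_sigma=noise_sigma,
        seed=seed,
        visible_min_arc_px=40.0,
    )
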