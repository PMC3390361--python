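"""Run configuration: every tunable of the pipeline with validated defaults.

Coordinate convention used everywhere: x = column, y = row, origin at the
center of the top-left pixel; sub-pixel positions are real-valued in this
frame.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class FaceSpec:
    """Where the face is, and which way whisker indices increase.

    ``side`` names the image edge occupied by the face (or "circle" for a
    circular face mask).  ``boundary_px`` is the coordinate of the mask
    boundary (x for left/right, y for top/bottom); ``None`` resolves to the
    image edge at run time.  ``anterior_positive`` says whether the
    anterior-posterior coordinate increases with the image axis along the
    face edge.
    """

    side: str = "bottom"
    boundary_px: float | None = None
    anterior_positive: bool = True
    circle_center: tuple | None = None
    circle_radius: float | None = None

    def __post_init__(self):
        if self.side not in ("left", "right", "top", "bottom", "circle"):
            raise ValueError(f"unknown face side {self.side!r}")
        if self.side == "circle" and (
            self.circle_center is None or self.circle_radius is None
        ):
            raise ValueError("circle face requires circle_center and circle_radius")


@dataclass
class RunConfig:
    """All pipeline tunables.  Field defaults are the values used throughout
    the test and acceptance suites."""

    # seeding
    grid_spacing_px: int = 50
    ecc_threshold: float = 0.95
    # detector lattice (informational; the bank is fixed at these)
    offset_step_px: float = 0.1
    width_step_px: float = 0.2
    angle_step_deg: float = 2.5
    detector_length_px: int = 20
    # tracing stop tests
    min_score_frac: float = 0.25  # of the frame intensity range
    max_asymmetry: float = 0.25
    min_mean_intensity: float = 0.35  # fraction of the frame mean
    max_angle_step_deg: float = 7.5
    max_gap_px: int = 8
    # redundant-curve resolution
    dedup_dist_px: float = 2.0
    dedup_frac: float = 0.5
    # preprocessing
    line_bias_correction: bool = True
    background_subtraction: bool = False
    # linking / measurement
    n_whiskers: int | None = None
    pixel_size_um: float = 1.0
    face: FaceSpec = field(default_factory=FaceSpec)
    follicle_extrapolation_px: float = 10.0
    interest_point_arc_mm: float = 5.0
    window_mm: float = 2.0
    pole: tuple | None = None  # (x, y, radius)
    # synthetic data only
    seed: int = 0

    def __post_init__(self):
        if self.grid_spacing_px < 1:
            raise ValueError("grid_spacing_px must be >= 1")
        if not (0.0 <= self.ecc_threshold <= 1.0):
            raise ValueError("ecc_threshold must be in [0, 1]")
        for name in (
            "min_score_frac",
            "max_asymmetry",
            "min_mean_intensity",
            "max_angle_step_deg",
            "dedup_dist_px",
            "pixel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_gap_px < 1:
            raise ValueError("max_gap_px must be >= 1")
        if not (0.0 < self.dedup_frac < 1.0):
            raise ValueError("dedup_frac must be in (0, 1)")
        if not (1.0 <= self.window_mm <= 2.5):
            raise ValueError("window_mm must be in [1, 2.5]")
        if self.n_whiskers is not None and self.n_whiskers < 1:
            raise ValueError("n_whiskers must be >= 1 when given")
        if isinstance(self.face, dict):
            self.face = FaceSpec(**self.face)

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        """Load from a JSON file or a simple ``key = value`` file."""
        with open(path) as fh:
            text = fh.read()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_dict(json.loads(text))
        d = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                d[key] = json.loads(val)
            except json.JSONDecodeError:
                d[key] = val
        return cls.from_dict(d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
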