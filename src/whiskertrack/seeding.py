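"""Detection of tracing-initiation sites.

A 7x7 box is slid over a sparse grid of image lines.  Within the box, two
partitions (the seven 1-px columns, and the seven 1-px rows) each collect the
position of the minimum-intensity pixel per strip.  When a dark line crosses
the box, one partition's minima line up along the backbone; the eccentricity
of the Gaussian fit to those minima scores line-likeness, and the major axis
gives the line orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgproc import Frame

BOX = 7
HALF = BOX // 2

# Minimum (box mean - box min) intensity contrast for a site to score at all.
# Strip minima in a near-uniform box land on tie-breaking positions, which are
# collinear by construction and would fake a perfect line; a dark backbone
# through the box always clears this easily.
MIN_CONTRAST = 10.0


@dataclass(frozen=True)
class Seed:
    """Candidate tracing-initiation site."""

    pos: tuple  # (x, y) integer pixel coordinates
    angle_deg: float  # line orientation, normalized to [0, 180)
    eccentricity: float  # in [0, 1]

    def __post_init__(self):
        if not (0.0 <= self.eccentricity <= 1.0):
            raise ValueError("eccentricity must be in [0, 1]")
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 180.0)


def box_minima_partitions(frame: Frame, center: tuple):
    """Strip minima of the 7x7 box centered at ``center`` = (x, y).

    Partition A: the 7 one-pixel-wide columns; partition B: the 7 rows.
    Returns (points_A, points_B), each a list of 7 (x, y) positions in image
    coordinates.  Ties resolve to the first pixel in row-major scan order
    within the strip (numpy argmin convention).
    """
    x, y = int(center[0]), int(center[1])
    h, w = frame.pixels.shape
    if not (HALF <= x < w - HALF and HALF <= y < h - HALF):
        raise ValueError(f"7x7 box at ({x}, {y}) does not fit inside the frame")
    patch = frame.pixels[y - HALF : y + HALF + 1, x - HALF : x + HALF + 1]
    rows_a = np.argmin(patch, axis=0)  # per-column minimum row
    cols_b = np.argmin(patch, axis=1)  # per-row minimum column
    points_a = [(x - HALF + j, y - HALF + int(rows_a[j])) for j in range(BOX)]
    points_b = [(x - HALF + int(cols_b[i]), y - HALF + i) for i in range(BOX)]
    return points_a, points_b


def eccentricity_and_orientation(points):
    """Eccentricity and major-axis angle of the covariance of 2-D points.

    With eigenvalues l1 >= l2 >= 0 of the 2x2 covariance,
    eccentricity = sqrt(1 - l2/l1) (0 when l1 == 0) and the angle is the
    orientation of the l1 eigenvector in degrees mod 180.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    n = pts.shape[0]
    a = (x * x).sum() / n
    b = (x * y).sum() / n
    c = (y * y).sum() / n
    return _ecc_angle_from_cov(a, b, c)


def _ecc_angle_from_cov(a, b, c):
    tr = a + c
    disc = np.sqrt(max((a - c) * (a - c) + 4.0 * b * b, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    if l1 <= 1e-12:
        return 0.0, 0.0
    ecc = float(np.sqrt(max(0.0, 1.0 - l2 / l1)))
    if abs(b) > 1e-12:
        vx, vy = b, l1 - a
    elif a >= c:
        vx, vy = 1.0, 0.0
    else:
        vx, vy = 0.0, 1.0
    angle = float(np.degrees(np.arctan2(vy, vx))) % 180.0
    return ecc, angle


def evaluate_sites(frame: Frame, xs: np.ndarray, ys: np.ndarray):
    """Vectorized eccentricity/orientation at many box centers.

    Returns (ecc, angle) arrays; centers must all admit a full 7x7 box.
    Constant boxes (no intensity structure) score 0: strip-minima positions
    are then pure tie-breaking artifacts, not evidence of a line.
    """
    img = frame.pixels
    h, w = img.shape
    xs = np.asarray(xs, dtype=np.intp)
    ys = np.asarray(ys, dtype=np.intp)
    if xs.size == 0:
        return np.empty(0), np.empty(0)
    if (xs < HALF).any() or (xs >= w - HALF).any() or (ys < HALF).any() or (
        ys >= h - HALF
    ).any():
        raise ValueError("some box centers do not fit inside the frame")
    off = np.arange(-HALF, HALF + 1)
    patches = img[
        (ys[:, None, None] + off[None, :, None]),
        (xs[:, None, None] + off[None, None, :]),
    ]  # (N, 7, 7) rows x cols
    flat = (patches.mean(axis=(1, 2)) - patches.min(axis=(1, 2))) < MIN_CONTRAST

    # a partition only counts when every one of its strips actually touches
    # the dark backbone: a line crossing the box darkens all transverse
    # strips, whereas a line *ending* inside the box leaves some strips
    # bright and their tie-break minima would corrupt the ellipse fit
    dark_thresh = 0.5 * (patches.mean(axis=(1, 2)) + patches.min(axis=(1, 2)))

    # partition A: column strips -> points (x=j, y=argmin_row)
    ra = np.argmin(patches, axis=1).astype(np.float64)  # (N, 7)
    ja = np.broadcast_to(np.arange(BOX, dtype=np.float64), ra.shape)
    ecc_a, ang_a = _batch_cov(ja, ra)
    valid_a = (patches.min(axis=1) < dark_thresh[:, None]).all(axis=1)
    ecc_a = np.where(valid_a, ecc_a, 0.0)
    # partition B: row strips -> points (x=argmin_col, y=i)
    cb = np.argmin(patches, axis=2).astype(np.float64)
    ib = np.broadcast_to(np.arange(BOX, dtype=np.float64), cb.shape)
    ecc_b, ang_b = _batch_cov(cb, ib)
    valid_b = (patches.min(axis=2) < dark_thresh[:, None]).all(axis=1)
    ecc_b = np.where(valid_b, ecc_b, 0.0)

    use_a = ecc_a >= ecc_b
    ecc = np.where(use_a, ecc_a, ecc_b)
    ang = np.where(use_a, ang_a, ang_b)
    ecc[flat] = 0.0
    ang[flat] = 0.0
    # center of the fitted ellipse (mean of the chosen partition's minima),
    # in image coordinates: the best on-backbone estimate at this site
    mean_x = np.where(use_a, ja.mean(axis=1), cb.mean(axis=1)) + xs - HALF
    mean_y = np.where(use_a, ra.mean(axis=1), ib.mean(axis=1)) + ys - HALF
    return ecc, ang, mean_x, mean_y


def _batch_cov(x, y):
    n = x.shape[1]
    mx = x.mean(axis=1, keepdims=True)
    my = y.mean(axis=1, keepdims=True)
    dx = x - mx
    dy = y - my
    a = (dx * dx).sum(axis=1) / n
    b = (dx * dy).sum(axis=1) / n
    c = (dy * dy).sum(axis=1) / n
    tr = a + c
    disc = np.sqrt(np.maximum((a - c) ** 2 + 4.0 * b * b, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.sqrt(np.clip(1.0 - l2 / np.where(l1 > 1e-12, l1, 1.0), 0.0, 1.0))
    ecc = np.where(l1 > 1e-12, ecc, 0.0)
    vx = np.where(np.abs(b) > 1e-12, b, np.where(a >= c, 1.0, 0.0))
    vy = np.where(np.abs(b) > 1e-12, l1 - a, np.where(a >= c, 0.0, 1.0))
    ang = np.degrees(np.arctan2(vy, vx)) % 180.0
    return ecc, ang


def grid_centers(shape: tuple, grid_spacing_px: int):
    """Valid box centers lying on the horizontal/vertical grid lines."""
    h, w = shape
    xs_valid = np.arange(HALF, w - HALF)
    ys_valid = np.arange(HALF, h - HALF)
    gx = np.arange(0, w, grid_spacing_px)
    gy = np.arange(0, h, grid_spacing_px)
    gx = gx[(gx >= HALF) & (gx < w - HALF)]
    gy = gy[(gy >= HALF) & (gy < h - HALF)]
    pts = set()
    for y in gy:  # horizontal lines
        for x in xs_valid:
            pts.add((int(x), int(y)))
    for x in gx:  # vertical lines
        for y in ys_valid:
            pts.add((int(x), int(y)))
    if not pts:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    arr = np.array(sorted(pts), dtype=np.intp)
    return arr[:, 0], arr[:, 1]


def find_seeds(frame: Frame, grid_spacing_px: int = 50, ecc_threshold: float = 0.95):
    """Seeds on the sparse evaluation grid, sorted by descending eccentricity.

    Ordering is made fully deterministic by breaking eccentricity ties on
    (y, x) position.
    """
    if grid_spacing_px < 1:
        raise ValueError("grid_spacing_px must be >= 1")
    if not (0.0 <= ecc_threshold <= 1.0):
        raise ValueError("ecc_threshold must be in [0, 1]")
    h, w = frame.pixels.shape
    xs, ys = grid_centers(frame.pixels.shape, grid_spacing_px)
    ecc, ang, mx, my = evaluate_sites(frame, xs, ys)
    keep = ecc > ecc_threshold
    # initiate tracing at the center of the fitted minima ellipse, which lies
    # on the backbone (the evaluation site itself can be a few px off it)
    px = np.clip(np.round(mx[keep]).astype(int), HALF, w - HALF - 1)
    py = np.clip(np.round(my[keep]).astype(int), HALF, h - HALF - 1)
    order = np.lexsort((px, py, -ecc[keep]))
    seeds = []
    seen = set()
    for i in order:
        pos = (int(px[i]), int(py[i]))
        if pos in seen:
            continue
        seen.add(pos)
        seeds.append(Seed(pos, float(ang[keep][i]), float(ecc[keep][i])))
    return seeds
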