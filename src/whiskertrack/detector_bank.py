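"""Pre-tabulated oriented line-detector bank.

The detector models a whisker as a rectangular intensity valley.  It is the
discrete Laplacian of that model: two parallel step-edge elements of length
20 px, separated by the detector width, each realized as an adjacent +1/-1
band pair (1 px thick; -1 inside the valley).  Stencils are the exact area
integral of this piecewise-constant function over each pixel square.  The
+/- band areas are equal, so every stencil sums to zero (offset
invariance).  All stencils share one constant scale (1/sqrt of the total
band area) that puts scores on the order of the image contrast; the
per-stencil magnitude is deliberately NOT normalized away — the relative
weight of stencil shapes is what makes the matched, centered configuration
outscore off-center ones.

Stencils are tabulated on a lattice: sub-pixel offset at 0.1 px, width at
0.2 px in [0.4, 6.0], angle at 2.5 degrees.  The bank is built lazily and
memoized per lattice point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .imgproc import Frame

OFFSET_STEP = 0.1
WIDTH_STEP = 0.2
ANGLE_STEP = 2.5
WIDTH_MIN = 0.4
WIDTH_MAX = 6.0
LENGTH_PX = 20

N_OFFSET = 10  # per axis: -0.5, -0.4, ..., 0.4
N_WIDTH = int(round((WIDTH_MAX - WIDTH_MIN) / WIDTH_STEP)) + 1  # 29
N_ANGLE = int(round(360.0 / ANGLE_STEP))  # 144

OFFSET_VALUES = np.round(np.arange(N_OFFSET) * OFFSET_STEP - 0.5, 10)
WIDTH_VALUES = np.round(WIDTH_MIN + np.arange(N_WIDTH) * WIDTH_STEP, 10)
ANGLE_VALUES = np.round(np.arange(N_ANGLE) * ANGLE_STEP, 10)

# Default local-search windows (lattice steps): +/-10 deg, +/-0.4 px.
ANGLE_WINDOW = 4
WIDTH_WINDOW = 2


@dataclass(frozen=True)
class DetectorParams:
    """A point on the detector lattice."""

    offset: tuple  # (ox, oy), each in [-0.5, 0.5), multiples of 0.1
    width_px: float
    angle_deg: float
    length_px: int = LENGTH_PX

    def indices(self):
        ox, oy = self.offset
        ix = _offset_index(ox)
        iy = _offset_index(oy)
        wi = _width_index(self.width_px)
        ai = _angle_index(self.angle_deg)
        return ai, wi, iy * N_OFFSET + ix


def _offset_index(v: float) -> int:
    i = int(round((v + 0.5) / OFFSET_STEP))
    if not (0 <= i < N_OFFSET) or abs(OFFSET_VALUES[i] - v) > 1e-9:
        raise ValueError(f"offset component {v} not on the 0.1 px lattice")
    return i


def _width_index(v: float) -> int:
    i = int(round((v - WIDTH_MIN) / WIDTH_STEP))
    if not (0 <= i < N_WIDTH) or abs(WIDTH_VALUES[i] - v) > 1e-9:
        raise ValueError(f"width {v} not on the 0.2 px lattice in [0.4, 6.0]")
    return i


def _angle_index(v: float) -> int:
    i = int(round((v % 360.0) / ANGLE_STEP)) % N_ANGLE
    if abs(((v % 360.0) - ANGLE_VALUES[i] + 180.0) % 360.0 - 180.0) > 1e-9:
        raise ValueError(f"angle {v} not on the 2.5 degree lattice")
    return i


def quantize_params(offset, width_px, angle_deg) -> DetectorParams:
    """Snap arbitrary continuous parameters to the nearest lattice point."""
    ox = OFFSET_VALUES[np.clip(int(round((offset[0] + 0.5) / OFFSET_STEP)), 0, N_OFFSET - 1)]
    oy = OFFSET_VALUES[np.clip(int(round((offset[1] + 0.5) / OFFSET_STEP)), 0, N_OFFSET - 1)]
    wi = np.clip(int(round((width_px - WIDTH_MIN) / WIDTH_STEP)), 0, N_WIDTH - 1)
    ai = int(round((angle_deg % 360.0) / ANGLE_STEP)) % N_ANGLE
    return DetectorParams((float(ox), float(oy)), float(WIDTH_VALUES[wi]), float(ANGLE_VALUES[ai]))


def params_from_indices(ai: int, wi: int, oi: int) -> DetectorParams:
    ox = float(OFFSET_VALUES[oi % N_OFFSET])
    oy = float(OFFSET_VALUES[oi // N_OFFSET])
    return DetectorParams((ox, oy), float(WIDTH_VALUES[wi]), float(ANGLE_VALUES[ai]))


def rasterize_detector(params: DetectorParams):
    """Pixel stencil of the detector at one lattice point.

    Returns (dx, dy, weight) arrays relative to the anchor pixel.  Weights
    sum to zero; all stencils carry the same constant scale.  Support is the
    set of pixels touched by any band.
    """
    ai, wi, oi = params.indices()  # validates lattice membership
    ox, oy = params.offset
    theta = math.radians(params.angle_deg)
    ct, st = math.cos(theta), math.sin(theta)
    hw = params.width_px / 2.0
    hl = params.length_px / 2.0
    ext_x = hl * abs(ct) + (hw + 1.0) * abs(st) + 1.0
    ext_y = hl * abs(st) + (hw + 1.0) * abs(ct) + 1.0
    x0 = int(math.floor(ox - ext_x))
    x1 = int(math.ceil(ox + ext_x))
    y0 = int(math.floor(oy - ext_y))
    y1 = int(math.ceil(oy + ext_y))
    nx = x1 - x0 + 1
    ny = y1 - y0 + 1
    raw = np.zeros((ny, nx))
    cov = np.zeros((ny, nx))
    _kernels.raster_detector_raw(ox, oy, ct, st, hw, hl, x0, y0, raw, cov)
    iy, ix = np.nonzero(cov > 1e-12)
    w = raw[iy, ix]
    w = w - w.sum() / w.size  # remove the tiny float residue of the area sums
    w = w / math.sqrt(4.0 * params.length_px)  # common scale for all stencils
    return (ix + x0).astype(np.int64), (iy + y0).astype(np.int64), w


def _offset_priority_order():
    """All 100 offset ids sorted by |offset| (tie: id), smallest first."""
    mags = []
    for oi in range(N_OFFSET * N_OFFSET):
        ox = OFFSET_VALUES[oi % N_OFFSET]
        oy = OFFSET_VALUES[oi // N_OFFSET]
        mags.append((round(ox * ox + oy * oy, 10), oi))
    return np.array([oi for _, oi in sorted(mags)], dtype=np.int64)


_ALL_OFFSETS_SORTED = _offset_priority_order()


def _offset_window_table(radius: int = 1):
    """table[oi] = (ids, anchor_dx, anchor_dy) within ``radius`` 0.1-px steps
    of offset oi, wrapping across pixel boundaries (an offset of +0.5 is the
    neighboring anchor at -0.5), sorted by the candidate's offset magnitude
    (the optimizer's tie-break order)."""
    table = []
    for oi in range(N_OFFSET * N_OFFSET):
        ix, iy = oi % N_OFFSET, oi // N_OFFSET
        cands = []
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                jx, jy = ix + dx, iy + dy
                sx, jx = divmod(jx, N_OFFSET)
                sy, jy = divmod(jy, N_OFFSET)
                o = jy * N_OFFSET + jx
                ox, oy = OFFSET_VALUES[jx], OFFSET_VALUES[jy]
                cands.append((round(ox * ox + oy * oy, 10), o, sx, sy))
        cands.sort()
        table.append(
            (
                np.array([c[1] for c in cands], dtype=np.int64),
                np.array([c[2] for c in cands], dtype=np.int64),
                np.array([c[3] for c in cands], dtype=np.int64),
            )
        )
    return table


_WINDOW_TABLE = _offset_window_table(1)
_NO_SHIFT = np.zeros(N_OFFSET * N_OFFSET, dtype=np.int64)


def offset_lattice_id(offset) -> int:
    """Nearest offset-lattice id for a continuous sub-pixel displacement."""
    ix = min(max(int(round((offset[0] + 0.5) / OFFSET_STEP)), 0), N_OFFSET - 1)
    iy = min(max(int(round((offset[1] + 0.5) / OFFSET_STEP)), 0), N_OFFSET - 1)
    return iy * N_OFFSET + ix


class DetectorBank:
    """Lazily built, memoized stencil bank with the per-step optimizer.

    All stencils share three flat buffers (pixel dx, dy, weight); a group =
    the 100 sub-pixel-offset stencils of one (angle, width) lattice point,
    addressed by a 101-entry pointer row into the buffers.  A search
    neighborhood is then just a stack of pointer rows, so the per-step scan
    is a single compiled call over plain arrays.
    """

    def __init__(self):
        self._stencils = {}  # (ai, wi, oi) -> (dx, dy, w)
        self._group_ptrs = {}  # (ai, wi) -> (101,) absolute buffer offsets
        self._neighborhoods = {}  # (ai, wi, width_window) -> (ptrs 2-D, meta)
        # flat stencil storage with amortized-doubling growth
        self._cap = 1 << 16
        self._size = 0
        self._buf_dx = np.empty(self._cap, dtype=np.int32)
        self._buf_dy = np.empty(self._cap, dtype=np.int32)
        self._buf_wt = np.empty(self._cap, dtype=np.float64)

    def _reserve(self, n: int) -> None:
        need = self._size + n
        if need <= self._cap:
            return
        while self._cap < need:
            self._cap *= 2
        for name in ("_buf_dx", "_buf_dy", "_buf_wt"):
            old = getattr(self, name)
            new = np.empty(self._cap, dtype=old.dtype)
            new[: self._size] = old[: self._size]
            setattr(self, name, new)

    # -- stencil / group construction ------------------------------------

    def stencil(self, params: DetectorParams):
        key = params.indices()
        st = self._stencils.get(key)
        if st is None:
            st = rasterize_detector(params)
            self._stencils[key] = st
        return st

    def _group(self, ai: int, wi: int) -> np.ndarray:
        key = (ai, wi)
        ptr = self._group_ptrs.get(key)
        if ptr is None:
            ptr = np.empty(N_OFFSET * N_OFFSET + 1, dtype=np.int64)
            ptr[0] = self._size
            for oi in range(N_OFFSET * N_OFFSET):
                dx, dy, w = rasterize_detector(params_from_indices(ai, wi, oi))
                n = dx.size
                self._reserve(n)
                s = self._size
                self._buf_dx[s : s + n] = dx
                self._buf_dy[s : s + n] = dy
                self._buf_wt[s : s + n] = w
                self._size = s + n
                ptr[oi + 1] = self._size
            self._group_ptrs[key] = ptr
        return ptr

    def _neighborhood(self, ai: int, wi: int, width_window: int = WIDTH_WINDOW):
        """Pointer stack for the local search window around (ai, wi).

        Groups are ordered by tie-break priority: smallest |angle change|
        first, then smallest |width change|, then positive change first.
        """
        key = (ai, wi, width_window)
        nb = self._neighborhoods.get(key)
        if nb is None:
            deltas = []
            for da in range(-ANGLE_WINDOW, ANGLE_WINDOW + 1):
                for dw in range(-width_window, width_window + 1):
                    if 0 <= wi + dw < N_WIDTH:
                        deltas.append((abs(da), abs(dw), -da, -dw, da, dw))
            deltas.sort()
            rows = []
            meta = []
            for _, _, _, _, da, dw in deltas:
                gai = (ai + da) % N_ANGLE
                gwi = wi + dw
                rows.append(self._group(gai, gwi))
                meta.append((gai, gwi))
            nb = (np.stack(rows), meta)
            self._neighborhoods[key] = nb
        return nb

    # -- evaluation ------------------------------------------------------

    def response(self, frame: Frame, anchor, params: DetectorParams) -> float:
        """Dot product of the stencil with the image at an integer anchor.

        Out-of-image pixels read as the frame mean (neutral under the
        zero-sum weighting).  Positive and maximal for a dark line of
        matching width/angle centered under the detector.
        """
        dx, dy, w = self.stencil(params)
        img = frame.pixels
        return float(
            _kernels.stencil_response(
                img, img.mean(), int(anchor[0]), int(anchor[1]), dx, dy, w
            )
        )

    def optimize_step(
        self,
        frame: Frame,
        anchor,
        prev: DetectorParams,
        offset_ids: np.ndarray | None = None,
        mean_intensity: float | None = None,
        width_window: int = WIDTH_WINDOW,
    ):
        """Local lattice search around ``prev`` at the given anchor.

        Searches angles within +/-10 deg, widths within +/-0.4 px and, by
        default, every sub-pixel offset.  Ties break toward the smallest
        change from ``prev`` (angle first, then width, then offset
        magnitude).  Returns (best_params, score).
        """
        ai, wi, _ = prev.indices()
        if offset_ids is None:
            offset_ids = _ALL_OFFSETS_SORTED
        params, score, _ = self._scan_window(
            frame,
            anchor,
            ai,
            wi,
            offset_ids,
            _NO_SHIFT[: offset_ids.size],
            _NO_SHIFT[: offset_ids.size],
            mean_intensity,
            width_window,
        )
        return params, score

    def optimize_local(
        self,
        frame: Frame,
        anchor,
        prev: DetectorParams,
        predicted_offset,
        mean_intensity: float | None = None,
        width_window: int = 1,
    ):
        """Per-step refinement around a predicted sub-pixel position.

        Searches the 3x3 offset window around ``predicted_offset`` (wrapping
        across pixel boundaries so axis-aligned drift is never blocked by
        the offset lattice edge), angles within +/-10 deg and widths within
        ``width_window`` lattice steps.  Returns (params, score, anchor):
        ``anchor`` is the pixel the winning stencil is anchored at.
        """
        ai, wi, _ = prev.indices()
        ids, adx, ady = _WINDOW_TABLE[offset_lattice_id(predicted_offset)]
        return self._scan_window(
            frame, anchor, ai, wi, ids, adx, ady, mean_intensity, width_window
        )

    def _scan_window(
        self, frame, anchor, ai, wi, offset_ids, adx, ady, mean_intensity, width_window
    ):
        ptrs, meta = self._neighborhood(ai, wi, width_window)
        img = frame.pixels
        if mean_intensity is None:
            mean_intensity = float(img.mean())
        g, k, score = _kernels.scan_groups(
            img,
            mean_intensity,
            int(anchor[0]),
            int(anchor[1]),
            self._buf_dx,
            self._buf_dy,
            self._buf_wt,
            ptrs,
            offset_ids,
            adx,
            ady,
        )
        gai, gwi = meta[g]
        used_anchor = (int(anchor[0]) + int(adx[k]), int(anchor[1]) + int(ady[k]))
        return params_from_indices(gai, gwi, int(offset_ids[k])), float(score), used_anchor

    def scan_widths(self, frame: Frame, anchor, angle_deg: float):
        """Joint scan over every width and every offset at a fixed angle.

        Used once per seed to initialize the detector width.  Returns
        (best_params, score).
        """
        ai = int(round((angle_deg % 360.0) / ANGLE_STEP)) % N_ANGLE
        ptrs = np.stack([self._group(ai, wi) for wi in range(N_WIDTH)])
        img = frame.pixels
        g, k, score = _kernels.scan_groups(
            img,
            float(img.mean()),
            int(anchor[0]),
            int(anchor[1]),
            self._buf_dx,
            self._buf_dy,
            self._buf_wt,
            ptrs,
            _ALL_OFFSETS_SORTED,
            _NO_SHIFT,
            _NO_SHIFT,
        )
        return params_from_indices(ai, int(g), int(_ALL_OFFSETS_SORTED[k])), float(score)
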