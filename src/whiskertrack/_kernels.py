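"""Numba-compiled inner loops: exact stencil rasterization and bank scans.

Everything here is deliberately free of Python objects so the tracing loop
stays fast.  Coordinates follow the package convention: x = column,
y = row, origin at the center of the top-left pixel.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import List as TypedList

__all__ = [
    "pixel_band_area",
    "raster_detector_raw",
    "scan_groups",
    "stencil_response",
    "TypedList",
]


@njit(cache=True)
def pixel_band_area(px, py, planes):
    """Area of the unit pixel square centered at (px, py) clipped by half-planes.

    ``planes`` is (K, 3); a point is kept when a*x + b*y + c <= 0.
    Sutherland-Hodgman on the convex pixel polygon; exact up to float error.
    """
    X = np.empty(12)
    Y = np.empty(12)
    X2 = np.empty(12)
    Y2 = np.empty(12)
    X[0] = px - 0.5
    Y[0] = py - 0.5
    X[1] = px + 0.5
    Y[1] = py - 0.5
    X[2] = px + 0.5
    Y[2] = py + 0.5
    X[3] = px - 0.5
    Y[3] = py + 0.5
    n = 4
    for k in range(planes.shape[0]):
        a = planes[k, 0]
        b = planes[k, 1]
        c = planes[k, 2]
        m = 0
        for i in range(n):
            j = i + 1
            if j == n:
                j = 0
            fi = a * X[i] + b * Y[i] + c
            fj = a * X[j] + b * Y[j] + c
            if fi <= 0.0:
                X2[m] = X[i]
                Y2[m] = Y[i]
                m += 1
                if fj > 0.0:
                    t = fi / (fi - fj)
                    X2[m] = X[i] + t * (X[j] - X[i])
                    Y2[m] = Y[i] + t * (Y[j] - Y[i])
                    m += 1
            elif fj <= 0.0:
                t = fi / (fi - fj)
                X2[m] = X[i] + t * (X[j] - X[i])
                Y2[m] = Y[i] + t * (Y[j] - Y[i])
                m += 1
        n = m
        if n == 0:
            return 0.0
        for i in range(n):
            X[i] = X2[i]
            Y[i] = Y2[i]
    area = 0.0
    for i in range(n):
        j = i + 1
        if j == n:
            j = 0
        area += X[i] * Y[j] - X[j] * Y[i]
    return abs(area) * 0.5


@njit(cache=True)
def raster_detector_raw(cx, cy, ct, st, half_w, half_len, x0, y0, out, cov):
    """Accumulate signed band areas of the two step-edge elements.

    The detector consists of four 1-px-thick bands of length 2*half_len along
    direction (ct, st) centered at (cx, cy): +1 bands just outside |v| = half_w,
    -1 bands just inside.  ``out`` receives signed area per pixel, ``cov`` the
    total absolute coverage (used to define the stencil support).
    Pixel (ix, iy) of ``out`` corresponds to image offset (x0+ix, y0+iy).
    """
    cu = ct * cx + st * cy
    cv = -st * cx + ct * cy
    planes = np.empty((4, 3))
    # u >= -half_len  and  u <= half_len
    planes[0, 0] = -ct
    planes[0, 1] = -st
    planes[0, 2] = cu - half_len
    planes[1, 0] = ct
    planes[1, 1] = st
    planes[1, 2] = -cu - half_len
    # v-range planes filled per band below
    vlo = np.empty(4)
    vhi = np.empty(4)
    sgn = np.empty(4)
    vlo[0] = half_w
    vhi[0] = half_w + 1.0
    sgn[0] = 1.0
    vlo[1] = half_w - 1.0
    vhi[1] = half_w
    sgn[1] = -1.0
    vlo[2] = -half_w - 1.0
    vhi[2] = -half_w
    sgn[2] = 1.0
    vlo[3] = -half_w
    vhi[3] = -half_w + 1.0
    sgn[3] = -1.0
    ny, nx = out.shape
    for iy in range(ny):
        for ix in range(nx):
            px = float(x0 + ix)
            py = float(y0 + iy)
            acc = 0.0
            cacc = 0.0
            for b in range(4):
                planes[2, 0] = st
                planes[2, 1] = -ct
                planes[2, 2] = cv + vlo[b]
                planes[3, 0] = -st
                planes[3, 1] = ct
                planes[3, 2] = -cv - vhi[b]
                a = pixel_band_area(px, py, planes)
                acc += sgn[b] * a
                cacc += a
            out[iy, ix] = acc
            cov[iy, ix] = cacc


@njit(cache=True)
def scan_groups(img, mean_intensity, ax, ay, buf_dx, buf_dy, buf_wt, ptrs, off_ids, adx, ady):
    """Best detector response over stencil groups near anchor (ax, ay).

    Stencils live in shared flat buffers; ``ptrs`` is (n_groups, 101): row g
    gives absolute buffer offsets of that group's 100 sub-pixel-offset
    stencils.  Candidate k evaluates offset id ``off_ids[k]`` at the shifted
    anchor (ax + adx[k], ay + ady[k]); the shifts let a sub-pixel search
    window wrap across pixel boundaries.  Groups and candidates must be
    pre-sorted by tie-break priority; strict ``>`` keeps the first
    (highest-priority) maximizer.  Out-of-image pixels read as
    ``mean_intensity``.  Returns (group index, candidate index, score).
    """
    H, W = img.shape
    best = -1.0e300
    best_g = -1
    best_k = -1
    # scores within this margin count as ties (float residue of the exact
    # zero-sum areas must not defeat the priority order)
    tie_eps = 1e-9
    for g in range(ptrs.shape[0]):
        for k in range(off_ids.shape[0]):
            o = off_ids[k]
            axk = ax + adx[k]
            ayk = ay + ady[k]
            s = 0.0
            for idx in range(ptrs[g, o], ptrs[g, o + 1]):
                x = axk + buf_dx[idx]
                y = ayk + buf_dy[idx]
                if 0 <= x < W and 0 <= y < H:
                    v = img[y, x]
                else:
                    v = mean_intensity
                s += buf_wt[idx] * v
            if s > best + tie_eps:
                best = s
                best_g = g
                best_k = k
    return best_g, best_k, best


@njit(cache=True)
def line_means(img, cx, cy, ct, st, half_len, vs, n_samples):
    """Mean bilinear-sampled intensity along lines parallel to the detector.

    Line j runs along direction (ct, st) through the point displaced by
    vs[j] along the normal (-st, ct) from (cx, cy).  Samples are clamped to
    the image border.
    """
    H, W = img.shape
    out = np.empty(vs.shape[0])
    for j in range(vs.shape[0]):
        bx = cx - st * vs[j]
        by = cy + ct * vs[j]
        acc = 0.0
        for i in range(n_samples):
            u = -half_len + 2.0 * half_len * i / (n_samples - 1)
            x = bx + u * ct
            y = by + u * st
            if x < 0.0:
                x = 0.0
            elif x > W - 1.0:
                x = W - 1.0
            if y < 0.0:
                y = 0.0
            elif y > H - 1.0:
                y = H - 1.0
            x0 = int(x)
            y0 = int(y)
            if x0 > W - 2:
                x0 = W - 2
            if y0 > H - 2:
                y0 = H - 2
            fx = x - x0
            fy = y - y0
            acc += (
                img[y0, x0] * (1 - fx) * (1 - fy)
                + img[y0, x0 + 1] * fx * (1 - fy)
                + img[y0 + 1, x0] * (1 - fx) * fy
                + img[y0 + 1, x0 + 1] * fx * fy
            )
        out[j] = acc / n_samples
    return out


@njit(cache=True)
def stencil_response(img, mean_intensity, ax, ay, dx, dy, wt):
    """Dot product of one stencil with the image at integer anchor (ax, ay)."""
    H, W = img.shape
    s = 0.0
    for idx in range(dx.shape[0]):
        x = ax + dx[idx]
        y = ay + dy[idx]
        if 0 <= x < W and 0 <= y < H:
            v = img[y, x]
        else:
            v = mean_intensity
        s += wt[idx] * v
    return s
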