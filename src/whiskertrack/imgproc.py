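"""Camera-artifact correction and optional background handling.

These corrections run before any tracing.  Images are stored as real-valued
arrays in the 8-bit intensity range; whiskers are dark on a bright
background throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

log = logging.getLogger(__name__)

MAX_INTENSITY = 255.0


@dataclass
class Frame:
    """One grayscale video frame.

    Attributes
    ----------
    pixels : (H, W) float array, intensities in [0, 255].
    frame_index : position of the frame in its video.
    pixel_size_um : physical size of one pixel (µm per px).
    """

    pixels: np.ndarray
    frame_index: int = 0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Frame.pixels must be 2-D")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"frame too small ({w}x{h}); minimum is 8x8")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame intensities must be finite")
        if self.pixels.min() < 0:
            raise ValueError("frame intensities must be >= 0")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Frame":
        return Frame(pixels, self.frame_index, self.pixel_size_um)


def correct_line_bias(frame: Frame) -> Frame:
    """Correct the fixed-pattern artifact where odd rows are darker.

    The gain is a single scalar estimated from the frame itself:
    g = mean(even rows) / mean(odd rows); odd rows (indices 1, 3, ...) are
    multiplied by g.  Output is clipped to [0, 255].
    """
    img = frame.pixels
    if img.shape[0] < 2:
        return frame
    even_mean = img[0::2].mean()
    odd_mean = img[1::2].mean()
    if odd_mean == 0.0:
        log.warning(
            "line-bias gain undefined (all-zero odd rows) in frame %d; "
            "returning frame unchanged",
            frame.frame_index,
        )
        return frame
    g = even_mean / odd_mean
    out = img.copy()
    out[1::2] *= g
    np.clip(out, 0.0, MAX_INTENSITY, out=out)
    return frame.with_pixels(out)


def estimate_background(video: Iterable[Frame]) -> Frame:
    """Per-pixel maximum intensity over the whole video.

    Because whiskers are dark and move, the running maximum converges to the
    whisker-free background.
    """
    bg = None
    first = None
    for i, frame in enumerate(video):
        if bg is None:
            first = frame
            bg = frame.pixels.copy()
        else:
            if frame.pixels.shape != bg.shape:
                raise ValueError(
                    f"frame {i} shape {frame.pixels.shape} does not match "
                    f"frame 0 shape {bg.shape}"
                )
            np.maximum(bg, frame.pixels, out=bg)
    if bg is None:
        raise ValueError("estimate_background requires at least one frame")
    return Frame(bg, 0, first.pixel_size_um)


def subtract_background(frame: Frame, background: Frame) -> Frame:
    """Remove static background, keeping whiskers dark on bright.

    out = MAX - clip(background - frame, 0, MAX); monotone in the input
    intensity so backbone minima stay minima.
    """
    if frame.pixels.shape != background.pixels.shape:
        raise ValueError(
            f"frame shape {frame.pixels.shape} does not match background "
            f"shape {background.pixels.shape}"
        )
    diff = np.clip(background.pixels - frame.pixels, 0.0, MAX_INTENSITY)
    return frame.with_pixels(MAX_INTENSITY - diff)


def preprocess(
    frame: Frame,
    line_bias: bool = True,
    background: Frame | None = None,
) -> Frame:
    """Standard preprocessing applied by the tracing pipeline."""
    out = frame
    if line_bias:
        out = correct_line_bias(out)
    if background is not None:
        out = subtract_background(out, background)
    return out
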