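"""Colormap assignment, TMI rasterization and contrast-amplified diffing.

Every brightness gradation gets a fixed color that depends only on the
gradation count and scheme name — never on image content — so transformed
images of different sources are directly comparable.  The default
rasterizer uses exact area-coverage anti-aliasing and keeps the float
pre-quantization buffer: a one-pixel edit of a large source image moves
square sides by ~1e-6 container units, far below the 8-bit quantization
step, and only the float buffer makes such edits provably detectable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .packing import PackedLayout

DEFAULT_SIZE = 450      # rendered TMI edge, pixels
DEFAULT_GAIN = 10.0     # contrast amplification of the subtraction image


@dataclass(frozen=True)
class ColorMap:
    """``entries[k]`` is the 8-bit RGB triple of gradation ``k``."""

    entries: np.ndarray
    scheme: str

    @property
    def levels(self) -> int:
        return int(self.entries.shape[0])


@dataclass(frozen=True)
class TmiImage:
    """Rendered transformed medical image.

    ``buffer`` holds per-channel float values before 8-bit quantization;
    all change detection runs on it.  ``pixels`` is the quantized view.
    """

    buffer: np.ndarray

    @property
    def pixels(self) -> np.ndarray:
        return np.clip(np.rint(self.buffer), 0, 255).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.buffer.shape[0], self.buffer.shape[1]


def _bluered(levels: int) -> np.ndarray:
    """Blue-to-red sweep, injective for every supported gradation count.

    The red channel carries the high-order bits of the gradation index (a
    monotone blue->red ramp); for more than 256 gradations the remaining
    low-order bits are folded into the low bits of the green channel, on
    top of a mid-peaked green ramp, so distinct gradations always map to
    distinct 24-bit colors.
    """
    k = np.arange(levels)
    low_bits = max(0, int(levels - 1).bit_length() - 8)
    if low_bits > 8:
        raise ValueError("gradation count above 2^16 is not supported")
    hi = k >> low_bits
    lo = k & ((1 << low_bits) - 1)
    t = hi / 255.0 if levels > 256 else k / (levels - 1)
    r = np.rint(255.0 * t).astype(np.int64)
    b = 255 - r
    g = np.rint(255.0 * (1.0 - np.abs(2.0 * t - 1.0))).astype(np.int64)
    if low_bits:
        mask = (1 << low_bits) - 1
        g = (g & ~mask) | lo
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def make_colormap(levels: int, scheme: str = "bluered") -> ColorMap:
    """Deterministic gradation -> RGB map for ``levels`` gradations.

    ``bluered`` (default) is injective; any matplotlib colormap name is
    also accepted (those give smoother figures but may repeat colors).
    """
    if levels < 2:
        raise ValueError("at least 2 gradations required")
    if scheme == "bluered":
        entries = _bluered(levels)
    else:
        import matplotlib

        try:
            cmap = matplotlib.colormaps[scheme]
        except KeyError:
            raise ValueError(f"unknown colormap scheme: {scheme!r}") from None
        rgba = cmap(np.linspace(0.0, 1.0, levels))
        entries = np.rint(rgba[:, :3] * 255.0).astype(np.uint8)
    return ColorMap(entries, scheme)


def _coverage(a0: float, a1: float, n: int) -> tuple[int, int, np.ndarray]:
    """Per-cell overlap of interval [a0, a1] with unit cells 0..n."""
    i0 = max(0, int(np.floor(a0)))
    i1 = min(n, int(np.ceil(a1)))
    if i1 <= i0:
        return 0, 0, np.empty(0)
    edges = np.arange(i0, i1 + 1, dtype=float)
    cov = np.minimum(a1, edges[1:]) - np.maximum(a0, edges[:-1])
    return i0, i1, np.clip(cov, 0.0, 1.0)


def render(layout: PackedLayout, colors: ColorMap,
           width: int = DEFAULT_SIZE, height: int = DEFAULT_SIZE,
           mode: str = "antialiased") -> TmiImage:
    """Rasterize a packed layout over a white background.

    The container [0, sqrt(2)]^2 is scaled to the output frame.  In
    ``antialiased`` mode each pixel blends square color and background by
    exact area coverage; ``nearest`` assigns each pixel the color of the
    square holding its center (hard edges, as in print figures).
    """
    if width < 1 or height < 1:
        raise ValueError("output dimensions must be positive")
    if mode not in ("antialiased", "nearest"):
        raise ValueError(f"unknown render mode: {mode!r}")
    buf = np.full((height, width, 3), 255.0)
    sx = width / layout.container_side
    sy = height / layout.container_side
    for sq in layout.squares:
        color = colors.entries[sq.level].astype(float)
        x0, x1 = sq.x * sx, (sq.x + sq.side) * sx
        y0, y1 = sq.y * sy, (sq.y + sq.side) * sy
        if mode == "antialiased":
            j0, j1, cx = _coverage(x0, x1, width)
            i0, i1, cy = _coverage(y0, y1, height)
            if cx.size == 0 or cy.size == 0:
                continue
            c = np.multiply.outer(cy, cx)[:, :, None]
            tile = buf[i0:i1, j0:j1]
            buf[i0:i1, j0:j1] = tile * (1.0 - c) + color * c
        else:
            j0 = max(0, int(np.ceil(x0 - 0.5)))
            j1 = min(width, int(np.ceil(x1 - 0.5)))
            i0 = max(0, int(np.ceil(y0 - 0.5)))
            i1 = min(height, int(np.ceil(y1 - 0.5)))
            buf[i0:i1, j0:j1] = color
    return TmiImage(buf)


def diff(a: TmiImage, b: TmiImage, gain: float = DEFAULT_GAIN) -> TmiImage:
    """Signed, gain-amplified subtraction image.

    Per channel: ``clip(128 + gain * (a - b), 0, 255)`` on the float
    buffers, so both signs of change are visible around mid-gray; identical
    inputs yield a uniform 128 image.
    """
    if a.buffer.shape != b.buffer.shape:
        raise ValueError("dimension mismatch between the two images")
    out = np.clip(128.0 + gain * (a.buffer - b.buffer), 0.0, 255.0)
    return TmiImage(out)


def buffer_to_csv(image: TmiImage, path) -> None:
    """Export the float buffer as ``row,col,r,g,b`` CSV for numeric work."""
    h, w = image.shape
    with open(Path(path), "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["row", "col", "r", "g", "b"])
        for i in range(h):
            for j in range(w):
                r, g, b = image.buffer[i, j]
                wr.writerow([i, j, repr(r), repr(g), repr(b)])
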