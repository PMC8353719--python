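"""Raster, ROI-polygon and landmark file I/O plus ROI pixel extraction.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, ``y`` increases downward, and pixel
centers sit at integer coordinates.  A pixel whose center lies exactly on a
polygon edge counts as inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

#: raster formats accepted by :func:`read_grayscale`
SUPPORTED_FORMATS = {"PNG", "TIFF", "PPM", "PGM", "JPEG"}


@dataclass(frozen=True)
class GrayscaleImage:
    """Integer-valued 2D raster with a declared brightness depth.

    ``bit_depth`` of ``b`` means ``L = 2**b`` brightness gradations; every
    pixel value must lie in ``[0, L-1]``.
    """

    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel values must be integers")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi >= self.levels:
            raise ValueError(
                f"pixel values [{lo}, {hi}] exceed the {self.bit_depth}-bit "
                f"range [0, {self.levels - 1}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def levels(self) -> int:
        return 1 << self.bit_depth

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def count(self) -> int:
        return self.pixels.size

    def values(self) -> "PixelCollection":
        """The full pixel multiset of the image."""
        return PixelCollection(self.pixels.ravel().copy(), self.levels)


@dataclass(frozen=True)
class PixelCollection:
    """A multiset of brightness values drawn from an ``levels``-gradation
    image (the raster geometry is deliberately forgotten: the brightness
    histogram is the only downstream consumer)."""

    values: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values).ravel()
        if v.size and (v.min() < 0 or v.max() >= self.levels):
            raise ValueError("values outside [0, levels-1]")
        object.__setattr__(self, "values", v)

    @property
    def count(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RoiPolygon:
    """A simple (non-self-intersecting) polygon delineating a zone of
    interest, vertices as (x, y) = (col, row) floats."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", v)

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class LandmarkSet:
    """Corresponding reference points between two images: ``src[i]`` maps
    to ``dst[i]``, coordinates as (x, y)."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.src, dtype=float))
        d = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if s.shape != d.shape or s.shape[1] != 2:
            raise ValueError("src and dst must be matching (N, 2) arrays")
        if s.shape[0] < 2:
            raise ValueError("at least 2 landmark pairs are required")
        object.__setattr__(self, "src", s)
        object.__setattr__(self, "dst", d)

    def __len__(self) -> int:
        return self.src.shape[0]


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    return 16


def read_grayscale(path, bit_depth: int | None = None) -> GrayscaleImage:
    """Read a grayscale raster (PNG, TIFF, PGM, JPEG).

    RGB inputs are rejected unless all channels are identical, in which case
    they collapse to one channel.  JPEG input is accepted with a warning:
    lossy recompression perturbs the very histogram the transform measures.
    ``bit_depth`` overrides the depth inferred from the file; values that
    exceed the declared depth are an error, never clipped.
    """
    path = Path(path)
    with Image.open(path) as img:
        fmt = img.format or ""
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(f"unsupported raster format: {fmt or path.suffix}")
        if fmt == "JPEG":
            log.warning(
                "%s is JPEG (lossy): decoded pixel values may differ from the "
                "original acquisition; histograms are affected", path
            )
        arr = np.asarray(img)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1])
                and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise ValueError("multi-channel image is not grayscale")
        arr = rgb[..., 0]
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
    return GrayscaleImage(arr.astype(np.int64), depth)


def write_grayscale(image: GrayscaleImage, path) -> None:
    """Write a grayscale image losslessly (PNG or PGM; 16-bit container for
    depths above 8)."""
    path = Path(path)
    if image.bit_depth <= 8:
        pil = Image.fromarray(image.pixels.astype(np.uint8), mode="L")
    else:
        pil = Image.fromarray(image.pixels.astype(np.uint16))
    pil.save(path)


def write_rgb(pixels: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 RGB raster as a lossless PNG."""
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise ValueError("expected (H, W, 3) uint8 RGB array")
    Image.fromarray(arr, mode="RGB").save(Path(path), format="PNG")


def read_rgb(path) -> np.ndarray:
    with Image.open(Path(path)) as img:
        return np.asarray(img.convert("RGB"))


def load_roi(path) -> RoiPolygon:
    """Load an ROI polygon from a text file: one ``x,y`` vertex per line,
    ``#`` starts a comment."""
    verts = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"malformed ROI vertex line: {raw!r}")
        verts.append((float(parts[0]), float(parts[1])))
    if len(verts) < 3:
        raise ValueError("ROI file holds fewer than 3 vertices")
    return RoiPolygon(np.array(verts))


def load_landmarks(path) -> LandmarkSet:
    """Load landmark pairs: one ``x_src,y_src,x_dst,y_dst`` line per pair."""
    src, dst = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [float(p) for p in line.split(",")]
        if len(parts) != 4:
            raise ValueError(f"malformed landmark line: {raw!r}")
        src.append(parts[:2])
        dst.append(parts[2:])
    return LandmarkSet(np.array(src), np.array(dst))


def extract_roi(image: GrayscaleImage, roi: RoiPolygon) -> PixelCollection:
    """Collect the values of all pixels whose centers fall inside or on the
    boundary of the polygon.

    Boundary inclusion makes the rule deterministic and easy to verify
    against a brute-force point-in-polygon tally.
    """
    v = roi.vertices
    if (v[:, 0].min() < 0 or v[:, 1].min() < 0
            or v[:, 0].max() > image.cols - 1 or v[:, 1].max() > image.rows - 1):
        raise ValueError("ROI polygon extends outside the image bounds")
    poly = roi.to_shapely()
    x0 = int(np.floor(v[:, 0].min()))
    x1 = int(np.ceil(v[:, 0].max()))
    y0 = int(np.floor(v[:, 1].min()))
    y1 = int(np.ceil(v[:, 1].max()))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    if not inside.any():
        raise ValueError("empty ROI: no pixel centers inside the polygon")
    vals = image.pixels[y0:y1 + 1, x0:x1 + 1].ravel()[inside]
    return PixelCollection(vals, image.levels)
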