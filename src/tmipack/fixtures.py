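"""Synthetic grayscale images and spectra with exactly prescribed
properties.

Every generator is a pure function of its parameters and seed, so any
worked-example histogram (e.g. a 945x1327 image holding exactly 5963
pixels of one gradation) is reproducible bit-exactly without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import GrayscaleImage
from .spectrum import BrightnessHistogram, NormalizedSpectrum, normalize


@dataclass(frozen=True)
class HistogramSpec:
    """Target histogram plus raster dimensions; counts must fill the
    raster exactly."""

    counts: np.ndarray
    rows: int
    cols: int
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if (c < 0).any():
            raise ValueError("negative count")
        if int(c.sum()) != self.rows * self.cols:
            raise ValueError(
                f"counts sum to {int(c.sum())}, raster holds "
                f"{self.rows * self.cols} pixels")
        object.__setattr__(self, "counts", c)

    @property
    def levels(self) -> int:
        return int(self.counts.size)


def _bit_depth_for(levels: int) -> int:
    return max(1, int(levels - 1).bit_length())


def image_from_histogram(spec: HistogramSpec) -> GrayscaleImage:
    """Build an image whose histogram equals the spec exactly: deal each
    gradation's count into a flat array, shuffle with the seed, reshape."""
    flat = np.repeat(np.arange(spec.levels), spec.counts)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(flat)
    return GrayscaleImage(flat.reshape(spec.rows, spec.cols),
                          _bit_depth_for(spec.levels))


def worked_example_image(rows: int = 945, cols: int = 1327,
                         level: int = 125, count: int = 5963,
                         levels: int = 256, seed: int = 0) -> GrayscaleImage:
    """The reference fixture: a rows x cols image with exactly ``count``
    pixels at ``level`` and the remainder at gradation 0."""
    counts = np.zeros(levels, dtype=np.int64)
    counts[level] = count
    counts[0] = rows * cols - count
    return image_from_histogram(HistogramSpec(counts, rows, cols, seed))


def gradient_image(rows: int, cols: int, levels: int) -> GrayscaleImage:
    """Left-to-right linear ramp quantized to ``levels`` gradations; column
    j holds gradation floor(j * levels / cols)."""
    if rows < 1 or cols < 1:
        raise ValueError("dimensions must be positive")
    col_levels = (np.arange(cols) * levels) // cols
    px = np.broadcast_to(col_levels, (rows, cols)).copy()
    return GrayscaleImage(px.astype(np.int64), _bit_depth_for(levels))


def random_histogram(levels: int, seed: int, total: int | None = None
                     ) -> BrightnessHistogram:
    """Seeded random partition of ``total`` pixels over the gradations
    (symmetric Dirichlet weights, multinomial counts)."""
    rng = np.random.default_rng(seed)
    if total is None:
        total = int(rng.integers(10_000, 1_000_000))
    weights = rng.dirichlet(np.ones(levels))
    counts = rng.multinomial(total, weights)
    return BrightnessHistogram(counts)


def random_spectrum(levels: int, seed: int) -> NormalizedSpectrum:
    """Seeded random normalized spectrum: a random partition of 1 into at
    most ``levels`` nonnegative fractions, reproducible from the seed."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    return normalize(random_histogram(levels, seed))


def random_image(rows: int, cols: int, levels: int,
                 seed: int) -> GrayscaleImage:
    """Uniform random image over the full gradation range."""
    rng = np.random.default_rng(seed)
    px = rng.integers(0, levels, size=(rows, cols))
    return GrayscaleImage(px.astype(np.int64), _bit_depth_for(levels))
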