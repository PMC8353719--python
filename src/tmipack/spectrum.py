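"""Brightness histogram and its normalized square-side spectrum.

This is the first half of the transform: count pixels per brightness
gradation, normalize the counts to area fractions ``p_k = c_k / N`` (which
abstracts from image size and sums to 1), take square sides ``s_k =
sqrt(p_k)``, and order the gradations by descending area.

Gradation index 0 is the minimum stored pixel value; the package never
reorders or inverts the stored brightness scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imaging_io import GrayscaleImage, PixelCollection


@dataclass(frozen=True)
class BrightnessHistogram:
    """Pixel counts per brightness gradation, ``counts[k]`` for k in 0..L-1."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a 1D vector")
        if (c < 0).any():
            raise ValueError("negative count")
        object.__setattr__(self, "counts", c)

    @property
    def levels(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Area fractions, square sides and the descending-area ordering.

    ``order`` is a permutation of the gradation indices, non-increasing in
    fraction, ties broken by ascending index; ``n_nonzero`` of its leading
    entries have positive fraction (zero-area gradations are parked at the
    end and skipped by the packer).
    """

    fractions: np.ndarray
    sides: np.ndarray
    order: np.ndarray
    n_nonzero: int

    @property
    def levels(self) -> int:
        return int(self.fractions.size)

    def packing_sequence(self) -> list[tuple[int, float]]:
        """Descending (gradation, side) pairs for the nonzero gradations."""
        return [(int(k), float(self.sides[k]))
                for k in self.order[: self.n_nonzero]]


def histogram(source, levels: int | None = None) -> BrightnessHistogram:
    """Tally pixel counts per brightness gradation.

    ``source`` is a :class:`GrayscaleImage`, :class:`PixelCollection` or a
    plain integer array; ``levels`` defaults to the source's own gradation
    count and every value must be below it.
    """
    if isinstance(source, GrayscaleImage):
        vals, default_levels = source.pixels.ravel(), source.levels
    elif isinstance(source, PixelCollection):
        vals, default_levels = source.values, source.levels
    else:
        vals = np.asarray(source).ravel()
        default_levels = None
    L = levels if levels is not None else default_levels
    if L is None:
        raise ValueError("levels must be given for a bare array")
    if vals.size == 0:
        raise ValueError("empty pixel collection")
    if vals.max() >= L or vals.min() < 0:
        raise ValueError(f"pixel value outside [0, {L - 1}]")
    return BrightnessHistogram(np.bincount(vals, minlength=L))


def order_descending(fractions: np.ndarray) -> np.ndarray:
    """Stable permutation sorting fractions non-increasingly; equal
    fractions keep ascending gradation order."""
    return np.argsort(-np.asarray(fractions), kind="stable")


def side_of(fraction: float) -> float:
    """Side of the square whose area is ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return float(np.sqrt(fraction))


def normalize(hist: BrightnessHistogram) -> NormalizedSpectrum:
    """Turn counts into the normalized spectrum (fractions, sides, order)."""
    N = hist.total
    if N < 1:
        raise ValueError("histogram is empty (total pixel count 0)")
    fractions = hist.counts / N
    sides = np.sqrt(fractions)
    order = order_descending(fractions)
    n_nonzero = int(np.count_nonzero(hist.counts))
    return NormalizedSpectrum(fractions, sides, order, n_nonzero)


def histogram_to_csv(hist: BrightnessHistogram, path) -> None:
    """Write ``level,count`` rows."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "count"])
        for k, c in enumerate(hist.counts):
            w.writerow([k, int(c)])


def histogram_from_csv(path) -> BrightnessHistogram:
    rows = {}
    with open(Path(path), newline="") as fh:
        for rec in csv.DictReader(fh):
            rows[int(rec["level"])] = int(rec["count"])
    L = max(rows) + 1
    counts = np.zeros(L, dtype=np.int64)
    for k, c in rows.items():
        counts[k] = c
    return BrightnessHistogram(counts)
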