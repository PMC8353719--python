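"""Perturbation experiments: edit a source image, quantify the data loss,
and measure the induced change in the transformed image.

"Removing" pixels acts on the pixel multiset, not on the raster shape: the
brightness histogram is the only downstream consumer, and multiset removal
matches the data-loss arithmetic (removed / total * 100 %).  Detection runs
on the float pre-quantization buffers of the two renderings; the quantized
gain-amplified subtraction image is produced for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import line as _bresenham_line

from ._util import round_sig
from .imaging_io import GrayscaleImage, PixelCollection
from .packing import pack
from .rendering import (DEFAULT_GAIN, DEFAULT_SIZE, TmiImage, diff,
                        make_colormap, render)
from .spectrum import histogram, normalize

KINDS = ("remove_column", "remove_row", "remove_segment",
         "remove_pixels", "set_pixel")


@dataclass(frozen=True)
class Perturbation:
    """One source-image edit.  Use the classmethod constructors."""

    kind: str
    params: dict

    @classmethod
    def remove_column(cls, col: int) -> "Perturbation":
        return cls("remove_column", {"col": int(col)})

    @classmethod
    def remove_row(cls, row: int) -> "Perturbation":
        return cls("remove_row", {"row": int(row)})

    @classmethod
    def remove_segment(cls, start: tuple[int, int],
                       end: tuple[int, int]) -> "Perturbation":
        """Remove the discrete line of pixels between two (x, y) endpoints,
        traced by the standard integer line-stepping (Bresenham) rule."""
        return cls("remove_segment", {"start": tuple(start), "end": tuple(end)})

    @classmethod
    def remove_pixels(cls, coords) -> "Perturbation":
        """Remove individual pixels given as (x, y) pairs."""
        return cls("remove_pixels", {"coords": [tuple(c) for c in coords]})

    @classmethod
    def set_pixel(cls, x: int, y: int, value: int) -> "Perturbation":
        return cls("set_pixel", {"x": int(x), "y": int(y), "value": int(value)})


@dataclass
class PerturbationReport:
    """Outcome of one perturbation experiment."""

    kind: str
    removed_count: int
    data_loss_percent: float
    spectrum_delta: list[tuple[int, float]]
    tmi_float_max_abs_diff: float
    tmi_changed_pixels: int
    seed: int | None = None

    @property
    def data_loss_percent_2sf(self) -> float:
        return round_sig(self.data_loss_percent, 2)


def _check_bounds(image: GrayscaleImage, x: int, y: int) -> None:
    if not (0 <= x < image.cols and 0 <= y < image.rows):
        raise ValueError(f"coordinate ({x}, {y}) outside the image")


def apply_perturbation(image: GrayscaleImage,
                       p: Perturbation) -> PixelCollection:
    """Return the pixel multiset after the edit.

    Removal kinds drop the targeted pixels from the multiset; ``set_pixel``
    keeps the count and replaces one value.
    """
    px = image.pixels
    if p.kind == "remove_column":
        col = p.params["col"]
        if not 0 <= col < image.cols:
            raise ValueError("column index out of bounds")
        keep = np.delete(px, col, axis=1)
        return PixelCollection(keep.ravel(), image.levels)
    if p.kind == "remove_row":
        row = p.params["row"]
        if not 0 <= row < image.rows:
            raise ValueError("row index out of bounds")
        keep = np.delete(px, row, axis=0)
        return PixelCollection(keep.ravel(), image.levels)
    if p.kind == "remove_segment":
        (x0, y0), (x1, y1) = p.params["start"], p.params["end"]
        _check_bounds(image, x0, y0)
        _check_bounds(image, x1, y1)
        rr, cc = _bresenham_line(y0, x0, y1, x1)
        mask = np.ones(px.shape, dtype=bool)
        mask[rr, cc] = False
        return PixelCollection(px[mask], image.levels)
    if p.kind == "remove_pixels":
        coords = p.params["coords"]
        mask = np.ones(px.shape, dtype=bool)
        for x, y in coords:
            _check_bounds(image, x, y)
            if not mask[y, x]:
                raise ValueError(f"pixel ({x}, {y}) removed twice")
            mask[y, x] = False
        return PixelCollection(px[mask], image.levels)
    if p.kind == "set_pixel":
        x, y, value = p.params["x"], p.params["y"], p.params["value"]
        _check_bounds(image, x, y)
        if not 0 <= value < image.levels:
            raise ValueError("new value outside the brightness range")
        out = px.copy()
        out[y, x] = value
        return PixelCollection(out.ravel(), image.levels)
    raise ValueError(f"unknown perturbation kind: {p.kind!r}")


def data_loss_percent(removed: int, total: int) -> float:
    """Removed pixels as a percentage of the original count, full
    precision (reporting helpers round to 2 significant figures)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= removed <= total:
        raise ValueError("removed must lie in [0, total]")
    return removed / total * 100.0


def perturbation_experiment(image: GrayscaleImage, p: Perturbation, *,
                            width: int = DEFAULT_SIZE,
                            height: int = DEFAULT_SIZE,
                            scheme: str = "bluered",
                            mode: str = "antialiased",
                            gain: float = DEFAULT_GAIN,
                            seed: int | None = None,
                            ) -> tuple[PerturbationReport, TmiImage]:
    """Run the full pipeline on the original and perturbed pixel multisets
    and report the induced spectrum and TMI changes.

    Returns the report and the gain-amplified subtraction image.
    """
    original = image.values()
    perturbed = apply_perturbation(image, p)

    spec0 = normalize(histogram(original))
    spec1 = normalize(histogram(perturbed))
    colors = make_colormap(image.levels)
    tmi0 = render(pack(spec0.packing_sequence()), colors, width, height, mode)
    tmi1 = render(pack(spec1.packing_sequence()), colors, width, height, mode)

    delta = tmi0.buffer - tmi1.buffer
    changed = int(np.count_nonzero(np.abs(delta).max(axis=2)))
    dp = spec1.fractions - spec0.fractions
    moved = np.flatnonzero(dp)
    removed = original.count - perturbed.count
    report = PerturbationReport(
        kind=p.kind,
        removed_count=removed,
        data_loss_percent=data_loss_percent(removed, original.count),
        spectrum_delta=[(int(k), float(dp[k])) for k in moved],
        tmi_float_max_abs_diff=float(np.abs(delta).max()),
        tmi_changed_pixels=changed,
        seed=seed,
    )
    return report, diff(tmi0, tmi1, gain)


def sequential_dot_deletions(image: GrayscaleImage, n: int = 10, *,
                             seed: int = 0, **render_kwargs
                             ) -> list[PerturbationReport]:
    """Delete ``n`` random pixels one at a time, re-running the experiment
    after each deletion (each report covers exactly one lost pixel,
    measured against the state just before it)."""
    rng = np.random.default_rng(seed)
    current = image
    reports = []
    for _ in range(n):
        y = int(rng.integers(current.rows))
        x = int(rng.integers(current.cols))
        rep, _ = perturbation_experiment(
            current, Perturbation.remove_pixels([(x, y)]),
            seed=seed, **render_kwargs)
        reports.append(rep)
        # materialize the deletion; only the multiset matters downstream,
        # so the survivors are carried as a single-column raster
        mask = np.ones(current.pixels.shape, dtype=bool)
        mask[y, x] = False
        current = GrayscaleImage(current.pixels[mask].reshape(-1, 1),
                                 current.bit_depth)
    return reports


def report_to_text(report: PerturbationReport, path=None) -> str:
    """Serialize a report as ``key: value`` lines (optionally to a file)."""
    lines = [
        f"kind: {report.kind}",
        f"removed_count: {report.removed_count}",
        f"data_loss_percent: {report.data_loss_percent!r}",
        f"data_loss_percent_2sf: {report.data_loss_percent_2sf!r}",
        f"tmi_float_max_abs_diff: {report.tmi_float_max_abs_diff!r}",
        f"tmi_changed_pixels: {report.tmi_changed_pixels}",
        f"seed: {report.seed}",
        "spectrum_delta:",
    ]
    lines += [f"  {k}: {d!r}" for k, d in report.spectrum_delta]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
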