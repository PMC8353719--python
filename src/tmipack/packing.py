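"""Shelf packing of a descending square sequence into a side-sqrt(2) box.

Any countable family of squares of total area <= 1 packs orthogonally,
without overlap, into a square of area 2 (Moon-Moser).  The constructive
proof is a shelf scheme and is the packer here: squares go left to right
into horizontal shelves, each shelf as tall as its first (largest) square;
a square that would overrun the container width opens a new shelf directly
below.  For a descending sequence with total area <= 1 the shelves provably
fit within the sqrt(2) height; the packer still asserts this at runtime.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SQRT2 = math.sqrt(2.0)

#: slack on the unit area budget, absorbing float drift in sums of c_k / N
AREA_TOL = 1e-9
_GEOM_EPS = 1e-12


@dataclass(frozen=True)
class PlacedSquare:
    """One packed square: brightness gradation, side, and top-left corner
    in container units (origin top-left, y downward)."""

    level: int
    side: float
    x: float
    y: float


@dataclass
class PackedLayout:
    squares: list[PlacedSquare]
    container_side: float = SQRT2
    shelves: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return float(sum(s.side * s.side for s in self.squares))

    @property
    def total_shelf_height(self) -> float:
        return float(sum(h for _, h in self.shelves))


@dataclass
class LayoutReport:
    """Findings of :func:`validate_layout`; empty everywhere iff valid."""

    overlaps: list[tuple[int, int]] = field(default_factory=list)
    containment: list[int] = field(default_factory=list)
    order_violations: list[int] = field(default_factory=list)
    area_excess: float = 0.0

    @property
    def ok(self) -> bool:
        return (not self.overlaps and not self.containment
                and not self.order_violations and self.area_excess == 0.0)


def pack(sides, container_side: float = SQRT2) -> PackedLayout:
    """Shelf-pack descending ``(level, side)`` pairs.

    Preconditions: sides non-increasing and positive, each side at most the
    container side, total area at most ``1 + AREA_TOL``.  A shelf overflow
    would contradict the area-2 theorem and raises ``RuntimeError``.
    """
    items = [(int(lv), float(s)) for lv, s in sides]
    layout = PackedLayout([], float(container_side), [])
    if not items:
        return layout
    sd = np.array([s for _, s in items])
    if (np.diff(sd) > _GEOM_EPS).any():
        raise ValueError("sides must be non-increasing")
    if (sd <= 0).any():
        raise ValueError("zero or negative side; drop empty gradations first")
    if sd[0] > container_side + _GEOM_EPS:
        raise ValueError("a square exceeds the container side")
    area = float(np.sum(sd * sd))
    if area > 1.0 + AREA_TOL:
        raise ValueError(f"total area {area} exceeds the unit budget")

    x = 0.0
    y = 0.0
    shelf_h = items[0][1]
    layout.shelves.append((y, shelf_h))
    for level, s in items:
        if x + s > container_side + _GEOM_EPS:
            y += shelf_h
            x = 0.0
            shelf_h = s
            layout.shelves.append((y, shelf_h))
        if y + s > container_side + AREA_TOL:
            raise RuntimeError(
                "shelf overflow: container height exceeded despite unit "
                "total area (theorem violation — internal error)"
            )
        layout.squares.append(PlacedSquare(level, s, x, y))
        x += s
    return layout


def validate_layout(layout: PackedLayout) -> LayoutReport:
    """Brute-force check of all structural guarantees of a layout:
    pairwise interior disjointness, containment, descending placement
    order, and the unit area budget."""
    rep = LayoutReport()
    n = len(layout.squares)
    if n == 0:
        return rep
    x = np.array([s.x for s in layout.squares])
    y = np.array([s.y for s in layout.squares])
    sd = np.array([s.side for s in layout.squares])

    bad = (x < -_GEOM_EPS) | (y < -_GEOM_EPS) | \
          (x + sd > layout.container_side + 1e-9) | \
          (y + sd > layout.container_side + 1e-9)
    rep.containment = list(np.flatnonzero(bad))

    rep.order_violations = list(np.flatnonzero(np.diff(sd) > _GEOM_EPS) + 1)

    # interiors overlap iff the projections overlap on both axes
    ox = np.minimum.outer(x + sd, x + sd) - np.maximum.outer(x, x) > _GEOM_EPS
    oy = np.minimum.outer(y + sd, y + sd) - np.maximum.outer(y, y) > _GEOM_EPS
    hit = np.triu(ox & oy, k=1)
    rep.overlaps = [(int(i), int(j)) for i, j in zip(*np.nonzero(hit))]

    excess = float(np.sum(sd * sd)) - (1.0 + AREA_TOL)
    rep.area_excess = max(0.0, excess)
    return rep


def layout_to_csv(layout: PackedLayout, path) -> None:
    """Write ``level,side,x,y`` rows at full float precision."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "side", "x", "y"])
        for s in layout.squares:
            w.writerow([s.level, repr(s.side), repr(s.x), repr(s.y)])
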