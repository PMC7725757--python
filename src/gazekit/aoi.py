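"""Areas of interest: rectangles, ellipses and polygons on the stimulus.

An AOI conditions fixation and reading parameters on a stimulus region.
Containment is boundary-inclusive for all shapes. Polygons use even-odd
ray casting with an on-edge short-circuit; vertices may describe any simple
polygon (self-intersection is not checked).

AOI tables are CSV files with columns ``stimulus, shape, coordinates``;
``coordinates`` is one quoted field holding the flattened numbers separated
by spaces:

* ``rectangle`` — ``x1 y1 x2 y2`` (top-left, bottom-right)
* ``ellipse``   — ``cx cy a b`` (center, semi-axes)
* ``polygon``   — ``x1 y1 x2 y2 x3 y3 ...`` (at least 3 vertices)

A later row for the same stimulus overrides an earlier one with a warning.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AOISpec", "contains_point", "load_aoi_table", "save_aoi_table", "parse_aoi_flag"]

_ARITY = {"rectangle": 4, "ellipse": 4}
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class AOISpec:
    """One region: ``shape`` in {rectangle, ellipse, polygon} plus its
    flattened coordinates."""

    shape: str
    coords: tuple

    def __post_init__(self):
        c = tuple(float(v) for v in self.coords)
        object.__setattr__(self, "coords", c)
        if self.shape == "rectangle":
            if len(c) != 4:
                raise ValueError("rectangle needs 4 numbers: x1 y1 x2 y2")
            x1, y1, x2, y2 = c
            if not (x1 < x2 and y1 < y2):
                raise ValueError("rectangle needs x1<x2 and y1<y2")
        elif self.shape == "ellipse":
            if len(c) != 4:
                raise ValueError("ellipse needs 4 numbers: cx cy a b")
            if c[2] <= 0 or c[3] <= 0:
                raise ValueError("ellipse semi-axes must be positive")
        elif self.shape == "polygon":
            if len(c) < 6 or len(c) % 2:
                raise ValueError("polygon needs >= 3 (x, y) vertex pairs")
        else:
            raise ValueError(f"unknown AOI shape {self.shape!r}")

    @property
    def vertices(self) -> list[tuple[float, float]]:
        if self.shape != "polygon":
            raise ValueError("vertices only defined for polygons")
        return [
            (self.coords[i], self.coords[i + 1]) for i in range(0, len(self.coords), 2)
        ]


def _on_segment(px, py, ax, ay, bx, by) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > _EDGE_EPS * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    return -_EDGE_EPS <= dot <= (bx - ax) ** 2 + (by - ay) ** 2 + _EDGE_EPS


def contains_point(aoi: AOISpec, p: tuple[float, float]) -> bool:
    """Boundary-inclusive containment test."""
    x, y = float(p[0]), float(p[1])
    if aoi.shape == "rectangle":
        x1, y1, x2, y2 = aoi.coords
        return x1 <= x <= x2 and y1 <= y <= y2
    if aoi.shape == "ellipse":
        cx, cy, a, b = aoi.coords
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    verts = aoi.vertices
    n = len(verts)
    inside = False
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if _on_segment(x, y, ax, ay, bx, by):
            return True  # boundary counts as inside
        if (ay > y) != (by > y):
            x_cross = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_cross:
                inside = not inside
    return inside


def save_aoi_table(aois: dict[str, AOISpec], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stimulus", "shape", "coordinates"])
        for stim, aoi in aois.items():
            writer.writerow(
                [stim, aoi.shape, " ".join(format(v, ".10g") for v in aoi.coords)]
            )
    return path


def load_aoi_table(path: str | Path) -> dict[str, AOISpec]:
    """Read a per-stimulus AOI CSV; later duplicate rows override earlier
    ones with a warning."""
    path = Path(path)
    out: dict[str, AOISpec] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "stimulus",
            "shape",
            "coordinates",
        ]:
            raise ValueError(f"{path}: expected header 'stimulus,shape,coordinates'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: row {lineno}: expected 3 fields")
            stim, shape, coord_text = row[0], row[1].strip(), row[2]
            try:
                coords = tuple(float(tok) for tok in coord_text.split())
                spec = AOISpec(shape, coords)
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
            if stim in out:
                warnings.warn(f"{path}: row {lineno}: duplicate AOI for {stim!r}, overriding")
            out[stim] = spec
    return out


def parse_aoi_flag(text: str) -> AOISpec | dict[str, AOISpec]:
    """Parse a CLI AOI flag: ``rect:x1,y1,x2,y2``, ``ellipse:cx,cy,a,b``,
    ``poly:x1,y1,...`` or ``file:aois.csv``."""
    kind, _, rest = text.partition(":")
    if kind == "file":
        return load_aoi_table(rest)
    shapes = {"rect": "rectangle", "ellipse": "ellipse", "poly": "polygon"}
    if kind not in shapes:
        raise ValueError(f"unknown AOI flag kind {kind!r}")
    coords = tuple(float(tok) for tok in rest.split(","))
    return AOISpec(shapes[kind], coords)
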