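"""Vector/raster domain objects shared by the generator and the connectivity model.

Raster convention: north-up, row 0 at the top, square cells of side
``cell_size`` metres, cell centres at half-integer grid coordinates.  The
planar coordinate of cell (row, col) is
``x = (col + 0.5) * cell_size``, ``y = (nrows - row - 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = ["Plot", "Road", "Inlet", "Site", "cell_center", "rasterize_polygon"]


@dataclass
class Plot:
    """A field plot: polygon with a crop label."""

    plot_id: str
    polygon: Polygon
    crop: str = "grain"


@dataclass
class Road:
    """A road/farm-track polyline with a surface class."""

    road_id: str
    line: LineString
    surface: str = "farm_track"  # "farm_track" | "concrete"


@dataclass
class Inlet:
    """A storm drainage inlet snapped to a raster cell."""

    inlet_id: str
    row: int
    col: int
    x: float
    y: float

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class Site:
    """A monitoring site and the contributing-area labels that feed it.

    An inlet site drains exactly its own label; the collector shaft drains
    the union of its member inlets; the stream site drains the "stream"
    label.
    """

    name: str
    point: Point
    dest_labels: tuple[str, ...]
    kind: str = "inlet"  # "inlet" | "collector" | "stream"
    stage_threshold_cm: float | None = None


def cell_center(row, col, nrows: int, cell_size: float):
    """Planar coordinates of cell centres (row/col may be arrays)."""
    x = (np.asarray(col) + 0.5) * cell_size
    y = (nrows - np.asarray(row) - 0.5) * cell_size
    return x, y


def rasterize_polygon(polygon: Polygon, nrows: int, ncols: int, cell_size: float) -> np.ndarray:
    """Boolean mask of cells whose centre falls inside the polygon."""
    import shapely

    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(minx / cell_size) - 1, 0)
    c1 = min(int(maxx / cell_size) + 2, ncols)
    r0 = max(int((nrows * cell_size - maxy) / cell_size) - 1, 0)
    r1 = min(int((nrows * cell_size - miny) / cell_size) + 2, nrows)
    mask = np.zeros((nrows, ncols), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = cell_center(rr, cc, nrows, cell_size)
    mask[r0:r1, c0:c1] = shapely.contains_xy(polygon, x, y)
    return mask
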