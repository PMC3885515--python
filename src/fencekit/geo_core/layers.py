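"""Typed vector layers and the density grid.

Thin dataclass wrappers around shapely geometries.  All coordinates are in a
single projected, metre-unit CRS; areas are reported in km² and fence totals
in km to match the thresholds used by the rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .errors import InvalidGeometryError

log = logging.getLogger(__name__)

AGENCIES = frozenset(
    {"private", "tribal", "state", "blm", "bor", "fws", "nps", "usfs", "water", "other"}
)
ROAD_CLASSES = frozenset({"primary", "secondary", "local"})
COVER_CLASSES = frozenset({"crop", "grassland", "shrubland", "mixed", "water"})
FENCE_SOURCES = frozenset({"tenure", "road", "landcover", "provided"})

#: agencies whose land is assumed unfenced (their outlines are dropped)
UNFENCED_AGENCIES = frozenset({"nps", "usfs"})


def repair_geometry(geom: BaseGeometry, what: str = "geometry") -> BaseGeometry:
    """Repair an invalid geometry, keeping only parts of the original dimension."""
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        parts = [g for g in fixed.geoms if g.geom_type.endswith(geom.geom_type.replace("Multi", ""))]
        if not parts:
            raise InvalidGeometryError(f"could not repair {what}")
        fixed = shapely.union_all(parts)
    log.info("repaired invalid %s", what)
    return fixed


def iter_polygons(geom: BaseGeometry) -> Iterable[Polygon]:
    if geom.is_empty:
        return
    if isinstance(geom, Polygon):
        yield geom
    elif isinstance(geom, MultiPolygon):
        yield from geom.geoms
    else:
        for g in getattr(geom, "geoms", ()):
            yield from iter_polygons(g)


def iter_lines(geom: BaseGeometry) -> Iterable[LineString]:
    if geom.is_empty:
        return
    if isinstance(geom, LineString):
        yield geom
    elif isinstance(geom, MultiLineString):
        yield from geom.geoms
    else:
        for g in getattr(geom, "geoms", ()):
            yield from iter_lines(g)


# ---------------------------------------------------------------------------
# feature records
# ---------------------------------------------------------------------------

@dataclass
class Parcel:
    geometry: BaseGeometry
    agency: str
    owner_id: str | None = None
    mailing_address: str | None = None
    area: float | None = None  # km²
    fid: int = 0
    fenced: bool = True

    def __post_init__(self) -> None:
        if self.agency not in AGENCIES:
            raise ValueError(f"unknown agency {self.agency!r}")
        if self.area is None:
            self.area = self.geometry.area / 1e6


@dataclass
class Road:
    geometry: LineString
    road_class: str
    length: float | None = None  # m
    fenced_flag: bool | None = None
    fid: int = 0

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {self.road_class!r}")
        if self.length is None:
            self.length = self.geometry.length


@dataclass
class CoverPatch:
    geometry: BaseGeometry
    cover_class: str
    fid: int = 0

    def __post_init__(self) -> None:
        if self.cover_class not in COVER_CLASSES:
            raise ValueError(f"unknown cover class {self.cover_class!r}")


@dataclass
class Fence:
    geometry: LineString
    source: str = "provided"
    fid: int = 0

    def __post_init__(self) -> None:
        if self.source not in FENCE_SOURCES:
            raise ValueError(f"unknown fence source {self.source!r}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

@dataclass
class ParcelSet:
    features: list[Parcel] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def total_area(self) -> float:
        """Total planar area in km²."""
        return sum(p.geometry.area for p in self.features) / 1e6

    def by_agency(self, *agencies: str) -> list[Parcel]:
        return [p for p in self.features if p.agency in agencies]

    def copy(self) -> "ParcelSet":
        return ParcelSet([replace(p) for p in self.features], self.crs)


@dataclass
class RoadNetwork:
    features: list[Road] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def total_length(self) -> float:
        """Total length in metres."""
        return sum(r.geometry.length for r in self.features)

    def by_class(self, *classes: str) -> list[Road]:
        return [r for r in self.features if r.road_class in classes]


@dataclass
class LandCoverMap:
    features: list[CoverPatch] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_class(self, *classes: str) -> list[CoverPatch]:
        return [c for c in self.features if c.cover_class in classes]


@dataclass
class FenceLayer:
    features: list[Fence] = field(default_factory=list)
    crs: str | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def total_length(self) -> float:
        """Total length in km."""
        return sum(f.geometry.length for f in self.features) / 1e3

    def by_source(self, *sources: str) -> "FenceLayer":
        return FenceLayer([f for f in self.features if f.source in sources], self.crs)

    def geometries(self) -> list[LineString]:
        return [f.geometry for f in self.features]

    def union(self) -> BaseGeometry:
        if not self.features:
            return MultiLineString([])
        return shapely.union_all(self.geometries())


def fences_from_geometry(
    geom: BaseGeometry, source: str, crs: str | None = None, min_len: float = 1e-9
) -> FenceLayer:
    """Explode arbitrary line-work into a FenceLayer of simple LineStrings."""
    feats = [
        Fence(g, source=source, fid=i)
        for i, g in enumerate(l for l in iter_lines(geom) if l.length > min_len)
    ]
    return FenceLayer(feats, crs)


# ---------------------------------------------------------------------------
# density grid
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """North-up raster of fence density (km of fence per km²).

    ``values[0, 0]`` is the north-west cell; ``origin`` is the projected
    coordinate of the grid's lower-left corner.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.values.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.values.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.origin[1] + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return xs, ys

    def valid_values(self) -> np.ndarray:
        return self.values[self.values != self.nodata]
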