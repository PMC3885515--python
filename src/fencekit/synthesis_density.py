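"""Fence layer synthesis and density estimation.

Combines tenure, land-cover and road fences (suppressing road fences that
duplicate nearby parcel fencing), handles water bodies, study-area edges,
exclusion areas and externally provided fences, then rasterises fence
density with a flat circular kernel: length within the search circle over
the circle's area, in km of fence per km².
"""

from __future__ import annotations

import logging
import math

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import MultiLineString, Point

from .geo_core import DensityGrid, Fence, FenceLayer, ModelConfig, iter_lines
from .geo_core.errors import CRSMismatchError

log = logging.getLogger(__name__)


def suppress_parallel_road_fences(
    road_fences: FenceLayer, other_fences: FenceLayer, config: ModelConfig
) -> FenceLayer:
    """Drop road fences that duplicate nearby parcel/land-cover fencing.

    A road fence feature is removed only when it lies *completely* within
    the suppression buffer of the other fencing; partial overlaps are kept
    in full.  A feature exactly on the buffer boundary is covered by it and
    is removed (deterministic boundary behaviour).
    """
    if not len(road_fences) or not len(other_fences):
        return FenceLayer(list(road_fences.features), road_fences.crs)
    buffer_zone = other_fences.union().buffer(config.parallel_suppress_dist)
    kept = [f for f in road_fences.features if not f.geometry.covered_by(buffer_zone)]
    log.info("parallel suppression: %d of %d road fences removed",
             len(road_fences) - len(kept), len(road_fences))
    return FenceLayer(
        [Fence(f.geometry, source="road", fid=i) for i, f in enumerate(kept)],
        road_fences.crs)


def _erase(features: list[Fence], eraser) -> list[Fence]:
    if eraser is None or eraser.is_empty:
        return features
    out = []
    for f in features:
        remainder = f.geometry.difference(eraser)
        for line in iter_lines(remainder):
            if line.length > 1e-9:
                out.append(Fence(line, source=f.source))
    return out


def synthesize(
    tenure: FenceLayer,
    landcover: FenceLayer,
    roads: FenceLayer,
    provided: FenceLayer | None = None,
    water=None,
    study_area=None,
    exclusion_mask=None,
    config: ModelConfig | None = None,
) -> FenceLayer:
    """Combine all fence sources into the final layer.

    Order: erase modeled fences inside the exclusion area; combine tenure
    and land-cover line-work (coincident segments counted once, tagged
    tenure); erase water bodies and segments lying on the study-area
    boundary; suppress road fences paralleling other fencing; merge roads;
    append provided fences unchanged.
    """
    config = config or ModelConfig()
    crss = {l.crs for l in (tenure, landcover, roads) if l.crs is not None}
    if provided is not None and provided.crs is not None:
        crss.add(provided.crs)
    if len(crss) > 1:
        raise CRSMismatchError(f"fence layers disagree on CRS: {sorted(crss)}")
    crs = next(iter(crss), None)

    tenure_feats = list(tenure.features)
    landcover_feats = list(landcover.features)
    road_feats = list(roads.features)
    if exclusion_mask is not None and not exclusion_mask.is_empty:
        tenure_feats = _erase(tenure_feats, exclusion_mask)
        landcover_feats = _erase(landcover_feats, exclusion_mask)
        road_feats = _erase(road_feats, exclusion_mask)

    # dedup land-cover line-work against tenure so coincident fences count once
    tenure_union = shapely.union_all([f.geometry for f in tenure_feats]) \
        if tenure_feats else MultiLineString([])
    deduped_landcover = []
    for f in landcover_feats:
        unique = f.geometry.difference(tenure_union)
        for line in iter_lines(unique):
            if line.length > 1e-9:
                deduped_landcover.append(Fence(line, source="landcover"))
    combined = tenure_feats + deduped_landcover

    if water is not None:
        water_union = shapely.union_all(list(water)) if not hasattr(water, "geom_type") else water
        combined = _erase(combined, water_union)
    if study_area is not None:
        edge_zone = study_area.boundary.buffer(config.length_tolerance)
        combined = _erase(combined, edge_zone)
        bounds_union = shapely.union_all([f.geometry for f in combined + road_feats]) \
            if combined + road_feats else MultiLineString([])
        if not bounds_union.is_empty and not bounds_union.within(study_area.buffer(1.0)):
            log.warning("study area does not cover all fences")

    other = FenceLayer(combined, crs)
    road_layer = suppress_parallel_road_fences(FenceLayer(road_feats, crs), other, config)

    feats = combined + list(road_layer.features)
    if provided is not None:
        feats += [Fence(f.geometry, source="provided") for f in provided.features]
    out = FenceLayer([Fence(f.geometry, f.source, fid=i) for i, f in enumerate(feats)], crs)
    log.info("synthesized fence layer: %.2f km in %d features",
             out.total_length, len(out))
    return out


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def fence_density(
    fences: FenceLayer, study_area, config: ModelConfig
) -> DensityGrid:
    """Flat-kernel line density on a cell grid covering the study area.

    Cell value = total fence length within the search circle centred on the
    cell / circle area, in km per km².  Cells whose centres fall outside the
    study area are nodata.  The grid origin snaps to the study-area
    bounding-box lower-left corner.
    """
    if config.density_search_radius <= 0 or config.density_cell_size <= 0:
        raise ValueError("density radius and cell size must be positive")
    if not len(fences):
        raise ValueError("fence layer is empty")
    minx, miny, maxx, maxy = study_area.bounds
    cell = config.density_cell_size
    radius = config.density_search_radius
    ncols = max(1, math.ceil((maxx - minx) / cell))
    nrows = max(1, math.ceil((maxy - miny) / cell))
    grid = DensityGrid(
        origin=(minx, miny), cell_size=cell,
        values=np.full((nrows, ncols), -9999.0), nodata=-9999.0)
    geoms = fences.geometries()
    tree = STRtree(geoms)
    circle_area_km2 = math.pi * (radius / 1e3) ** 2
    shapely.prepare(study_area)
    for row in range(nrows):
        for col in range(ncols):
            cx, cy = grid.cell_center(row, col)
            if not shapely.contains_xy(study_area, cx, cy):
                continue
            circle = Point(cx, cy).buffer(radius, quad_segs=64)
            length_m = 0.0
            for idx in tree.query(circle, predicate="intersects"):
                length_m += geoms[idx].intersection(circle).length
            grid.values[row, col] = (length_m / 1e3) / circle_area_km2
    log.info("density grid %dx%d, mean %.3f km/km2", nrows, ncols,
             float(np.mean(grid.valid_values())) if grid.valid_values().size else 0.0)
    return grid


def zonal_density_stats(grid: DensityGrid, zones: dict) -> list[dict]:
    """Per-zone mean and max over cells whose centres fall in the zone.

    ``zones`` maps zone id -> polygon.  A global row (zone_id ``__all__``)
    is appended.  Zones containing no cell centres get null stats.
    """
    xs, ys = grid.cell_centers()
    rows = []
    for zone_id, poly in zones.items():
        vals = []
        for r, y in enumerate(ys):
            for c, x in enumerate(xs):
                if grid.values[r, c] != grid.nodata and shapely.contains_xy(poly, x, y):
                    vals.append(grid.values[r, c])
        if vals:
            rows.append({"zone_id": zone_id, "mean": float(np.mean(vals)),
                         "max": float(np.max(vals)), "n_cells": len(vals)})
        else:
            log.info("zone %r contains no cell centres", zone_id)
            rows.append({"zone_id": zone_id, "mean": None, "max": None, "n_cells": 0})
    valid = grid.valid_values()
    rows.append({
        "zone_id": "__all__",
        "mean": float(np.mean(valid)) if valid.size else None,
        "max": float(np.max(valid)) if valid.size else None,
        "n_cells": int(valid.size),
    })
    return rows
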