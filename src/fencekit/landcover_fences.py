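"""Land-cover fence rules.

Cropland is consolidated (small non-crop inclusions absorbed into large
crop bodies), fences are drawn between large croplands and large native
prairie, and tenure fencing is masked out of large cropland interiors.
"""

from __future__ import annotations

import logging

import shapely
from shapely.geometry import Polygon

from .geo_core import FenceLayer, LandCoverMap, ModelConfig, fences_from_geometry
from .geo_core.errors import RasterResolutionError
from .geo_core.layers import Fence, iter_lines, iter_polygons
from .geo_core.outlines import boundary_linework

log = logging.getLogger(__name__)


def _dissolved_parts(geometries) -> list[Polygon]:
    if not geometries:
        return []
    return list(iter_polygons(shapely.union_all(geometries)))


def consolidate_cropland(landcover: LandCoverMap, config: ModelConfig) -> list[Polygon]:
    """Absorb small non-crop inclusions and return the large crop bodies.

    Non-crop polygons no larger than half a section that intersect a crop
    body of at least three sections are dissolved into it; crop bodies below
    three sections are discarded.
    """
    crop_parts = _dissolved_parts([c.geometry for c in landcover.by_class("crop")])
    if not crop_parts:
        return []
    large = [p for p in crop_parts if p.area / 1e6 >= config.three_sections_area]
    if not large:
        return []
    noncrop_classes = sorted({c.cover_class for c in landcover} - {"crop"})
    absorbed = []
    for cls in noncrop_classes:
        for part in _dissolved_parts([c.geometry for c in landcover.by_class(cls)]):
            if part.area / 1e6 > config.half_section_area:
                continue
            if any(part.intersects(big) for big in large):
                absorbed.append(part)
    merged = _dissolved_parts(large + absorbed)
    result = [p for p in merged if p.area / 1e6 >= config.three_sections_area]
    log.info("large croplands: %d bodies, %d inclusions absorbed", len(result), len(absorbed))
    return result


def fill_residual_holes(
    large_crop: list[Polygon], config: ModelConfig
) -> list[Polygon]:
    """Remove any interior holes remaining in the large crop bodies.

    Equivalent to rasterising at ``hole_fill_cell_size``, expanding from
    within and re-vectorising, but computed exactly in vector space so the
    exterior is preserved without quantisation.  The raster-feasibility
    precondition is still enforced: the nominal cell must not exceed the
    smallest polygon.
    """
    cell_area = config.hole_fill_cell_size ** 2
    for i, poly in enumerate(large_crop):
        if poly.area < cell_area:
            raise RasterResolutionError(
                f"hole-fill cell size {config.hole_fill_cell_size} m exceeds "
                f"polygon {i} (area {poly.area:.1f} m2)")
    return [Polygon(p.exterior) for p in large_crop]


def crop_prairie_fences(
    large_crop: list[Polygon],
    landcover: LandCoverMap,
    config: ModelConfig,
) -> tuple[FenceLayer, list[Polygon]]:
    """Fences between large croplands and large native prairie.

    Prairie bodies (grassland/shrubland/mixed by default) strictly larger
    than half a section are erased from the crop bodies; the boundaries of
    what remains are the land-cover fences.  Returns the fences and the
    final crop polygons.
    """
    if not large_crop:
        return FenceLayer([], landcover.crs), []
    prairie_parts = _dissolved_parts([
        c.geometry for c in landcover.by_class(*config.prairie_classes)
    ])
    big_prairie = [p for p in prairie_parts if p.area / 1e6 > config.half_section_area]
    if big_prairie:
        eraser = shapely.union_all(big_prairie)
        final = []
        for poly in large_crop:
            remainder = poly.difference(eraser)
            final.extend(iter_polygons(remainder))
    else:
        final = list(large_crop)
    fences = fences_from_geometry(
        boundary_linework(final), source="landcover", crs=landcover.crs)
    log.info("landcover fences: %.2f km around %d crop bodies",
             fences.total_length, len(final))
    return fences, final


def mask_tenure_in_crop(
    tenure_fences: FenceLayer, large_crop: list[Polygon]
) -> FenceLayer:
    """Delete tenure fence portions strictly inside large croplands.

    Portions lying exactly on a crop boundary are retained — the boundary
    itself is a modeled fence.
    """
    if not large_crop or not len(tenure_fences):
        return FenceLayer(list(tenure_fences.features), tenure_fences.crs)
    crop_union = shapely.union_all(large_crop)
    boundary = crop_union.boundary
    feats = []
    for f in tenure_fences.features:
        outside = f.geometry.difference(crop_union)
        on_edge = f.geometry.intersection(boundary)
        kept = shapely.union_all([g for g in
                                  list(iter_lines(outside)) + list(iter_lines(on_edge))])
        for line in iter_lines(kept):
            if line.length > 1e-9:
                feats.append(Fence(line, source="tenure", fid=len(feats)))
    out = FenceLayer(feats, tenure_fences.crs)
    log.info("tenure masking: %.2f km kept of %.2f km",
             out.total_length, tenure_fences.total_length)
    return out


def build_landcover_fences(
    landcover: LandCoverMap,
    tenure_fences: FenceLayer,
    config: ModelConfig,
) -> tuple[FenceLayer, FenceLayer, list[Polygon]]:
    """Full land-cover stage: (landcover fences, masked tenure fences, crop polys)."""
    large = consolidate_cropland(landcover, config)
    large = fill_residual_holes(large, config)
    lc_fences, final_crop = crop_prairie_fences(large, landcover, config)
    masked_tenure = mask_tenure_in_crop(tenure_fences, final_crop)
    return lc_fences, masked_tenure, final_crop
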