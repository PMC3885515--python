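"""Shared boundary line-work extraction.

A fence between two adjacent parcels is one fence: outlines are produced by
unioning all polygon boundaries, which nodes and deduplicates shared edges,
rather than by concatenating per-feature perimeters.
"""

from __future__ import annotations

import shapely
from shapely.geometry import MultiLineString
from shapely.ops import linemerge

from .layers import FenceLayer, ParcelSet, fences_from_geometry


def boundary_linework(geometries) -> shapely.geometry.base.BaseGeometry:
    """Union of polygon boundaries: shared edges appear exactly once."""
    boundaries = [g.boundary for g in geometries if not g.is_empty]
    if not boundaries:
        return MultiLineString([])
    merged = shapely.union_all(boundaries)
    if merged.is_empty:
        return MultiLineString([])
    out = linemerge(merged) if merged.geom_type == "MultiLineString" else merged
    return out


def polygon_outlines(parcels: ParcelSet, source: str = "tenure") -> FenceLayer:
    """Emit the deduplicated outlines of all fenced parcels as a FenceLayer."""
    geoms = [p.geometry for p in parcels.features if p.fenced]
    return fences_from_geometry(boundary_linework(geoms), source=source, crs=parcels.crs)
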