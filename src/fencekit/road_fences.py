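"""Road fence construction.

Primary and secondary roads (plus long local roads) get fences on both
sides, built as flat-capped buffers whose boundaries are converted to lines;
the square buffer ends — segments exactly two half-widths long — are deleted
so fences never bisect a road.  Fenced local roads keep a single offset line
on one side.
"""

from __future__ import annotations

import logging

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import LineString, MultiLineString
from shapely.ops import linemerge

from .geo_core import Fence, FenceLayer, ModelConfig, Road, RoadNetwork, iter_lines

log = logging.getLogger(__name__)


def _ring_edges(ring) -> list[LineString]:
    coords = list(ring.coords)
    return [LineString(coords[i:i + 2]) for i in range(len(coords) - 1)]


def _buffer_to_fences(buffer_geom, cap_lengths, tolerance: float):
    """Explode a dissolved buffer boundary into edges, drop cap-length edges,
    and re-merge the survivors."""
    kept = []
    for poly in getattr(buffer_geom, "geoms", [buffer_geom]):
        for ring in [poly.exterior, *poly.interiors]:
            for edge in _ring_edges(ring):
                if any(abs(edge.length - cap) <= tolerance for cap in cap_lengths):
                    continue
                if edge.length > tolerance:
                    kept.append(edge)
    if not kept:
        return MultiLineString([])
    merged = linemerge(MultiLineString(kept))
    return merged


def double_sided_fences(roads: RoadNetwork, config: ModelConfig) -> FenceLayer:
    """Two offset fence lines along every primary/secondary/long-local road.

    Buffers are built per class half-width, dissolved together across
    classes, and converted to lines; boundary segments matching any class cap
    length are removed.
    """
    buffers = []
    cap_lengths = set()
    for road in roads.features:
        if road.geometry.length <= config.length_tolerance:
            log.warning("skipping zero-length road %d", road.fid)
            continue
        halfwidth = config.halfwidth_for(road.road_class)
        cap_lengths.add(config.cap_len_for(road.road_class))
        buffers.append(
            road.geometry.buffer(halfwidth, cap_style="flat", join_style="mitre"))
    if not buffers:
        return FenceLayer([], roads.crs)
    dissolved = shapely.union_all(buffers)
    linework = _buffer_to_fences(dissolved, cap_lengths, config.length_tolerance)
    feats = [Fence(g, source="road", fid=i) for i, g in enumerate(iter_lines(linework))]
    return FenceLayer(feats, roads.crs)


def classify_fenced_local_roads(
    roads: RoadNetwork,
    config: ModelConfig,
    exclusion_mask=None,
) -> RoadNetwork:
    """Select the local roads assumed fenced.

    Local roads inside the exclusion mask are removed.  Roads at least
    ``long_local_min_len`` seed the selection; any unselected local road that
    intersects a selected one (including endpoint touches) is added,
    iterated to a fixpoint.
    """
    locals_ = roads.by_class("local")
    if exclusion_mask is not None and not exclusion_mask.is_empty:
        locals_ = [r for r in locals_ if not r.geometry.within(exclusion_mask)]
    if not locals_:
        return RoadNetwork([], roads.crs)
    geoms = [r.geometry for r in locals_]
    marked = np.array([g.length >= config.long_local_min_len for g in geoms])
    if not marked.any():
        return RoadNetwork([], roads.crs)
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    neighbours: dict[int, set[int]] = {}
    for i, j in zip(left.tolist(), right.tolist()):
        if i != j:
            neighbours.setdefault(i, set()).add(j)
    frontier = list(np.flatnonzero(marked))
    while frontier:
        i = frontier.pop()
        for j in neighbours.get(i, ()):
            if not marked[j]:
                marked[j] = True
                frontier.append(j)
    selected = [
        Road(geometry=r.geometry, road_class="local", fenced_flag=True, fid=k)
        for k, r in enumerate(r for r, m in zip(locals_, marked) if m)
    ]
    log.info("fenced local roads: %d of %d", len(selected), len(locals_))
    return RoadNetwork(selected, roads.crs)


def one_sided_local_fences(
    fenced_locals: RoadNetwork, config: ModelConfig
) -> FenceLayer:
    """One offset fence line per fenced local road.

    Which side survives is unspecified by the source rules; the default is
    the left side relative to digitised direction (configurable to right or
    seeded random).
    """
    rng = np.random.default_rng(config.local_fence_side_seed)
    feats = []
    for road in fenced_locals.features:
        if road.geometry.length <= config.length_tolerance:
            continue
        side = config.local_fence_side
        if side == "random":
            side = "left" if rng.random() < 0.5 else "right"
        distance = config.local_halfwidth if side == "left" else -config.local_halfwidth
        offset = road.geometry.offset_curve(distance, join_style="mitre")
        for line in iter_lines(offset):
            if line.length > config.length_tolerance:
                feats.append(Fence(line, source="road", fid=len(feats)))
    return FenceLayer(feats, fenced_locals.crs)


def build_road_fences(
    roads: RoadNetwork,
    config: ModelConfig,
    exclusion_mask=None,
) -> FenceLayer:
    """Full road fence model: double-sided majors + one-sided short locals."""
    fenced_locals = classify_fenced_local_roads(roads, config, exclusion_mask)
    long_locals = [
        r for r in fenced_locals.features
        if r.geometry.length >= config.long_local_min_len
    ]
    short_locals = [
        r for r in fenced_locals.features
        if r.geometry.length < config.long_local_min_len
    ]
    majors = RoadNetwork(
        roads.by_class("primary", "secondary") + long_locals, roads.crs)
    double = double_sided_fences(majors, config)
    single = one_sided_local_fences(RoadNetwork(short_locals, roads.crs), config)
    feats = [
        Fence(f.geometry, source="road", fid=i)
        for i, f in enumerate(double.features + single.features)
    ]
    layer = FenceLayer(feats, roads.crs)
    log.info("road fences: %.2f km (%d double-sided inputs, %d one-sided)",
             layer.total_length, len(majors), len(short_locals))
    return layer
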