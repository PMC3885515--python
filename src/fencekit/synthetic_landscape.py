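"""Fully synthetic model inputs.

Generates checkerboard section tenure, classed road grids, crop/prairie
mosaics, ground-truth fences (the model's own output, optionally perturbed)
and simulated GPS surveys, so the whole pipeline and the kappa-recovery
tests run without any external data.

Layout conventions (all deterministic under the seed):

* sections are exact squares of side sqrt(section area), anchored at the
  extent's lower-left corner;
* grid roads run parallel to section lines at a small inward offset, so
  road fences never coincide with parcel fencing;
* short attached road stubs hang off local grid roads; isolated stubs sit
  in section interiors well away from any fence (the guaranteed non-fenced
  survey strata).
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import LineString, Point, Polygon, box

from .geo_core import (
    CoverPatch,
    Fence,
    FenceLayer,
    LandCoverMap,
    ModelConfig,
    Parcel,
    ParcelSet,
    Road,
    RoadNetwork,
)
from .landcover_fences import build_landcover_fences
from .road_fences import build_road_fences
from .survey_accuracy import SurveyPoint, Transect
from .synthesis_density import synthesize
from .tenure_fences import TenureRuleLedger, build_tenure_fences

log = logging.getLogger(__name__)

DEFAULT_CRS = "EPSG:32613"

DEFAULT_AGENCY_MIX = {
    "private": 0.55, "state": 0.12, "blm": 0.15, "tribal": 0.08,
    "nps": 0.04, "usfs": 0.02, "fws": 0.02, "bor": 0.02,
}
DEFAULT_CLASS_MIX = {"primary": 0.15, "secondary": 0.35, "local": 0.5}


def section_side(section_area_km2: float = 2.59) -> float:
    return math.sqrt(section_area_km2 * 1e6)


def _grid_shape(extent, side: float) -> tuple[int, int]:
    xmin, ymin, xmax, ymax = extent
    nx = int((xmax - xmin) / side + 1e-9)
    ny = int((ymax - ymin) / side + 1e-9)
    if nx < 2 or ny < 2:
        raise ValueError("extent must cover at least 2x2 sections")
    return nx, ny


def sections_extent(n_cols: int, n_rows: int, section_area_km2: float = 2.59,
                    origin: tuple[float, float] = (0.0, 0.0)) -> tuple:
    """Convenience: the extent of an n_cols x n_rows section grid."""
    side = section_side(section_area_km2)
    return (origin[0], origin[1], origin[0] + n_cols * side, origin[1] + n_rows * side)


# ---------------------------------------------------------------------------
# tenure
# ---------------------------------------------------------------------------

def generate_tenure(
    extent,
    seed: int,
    agency_mix: dict[str, float] | None = None,
    owner_pool: int = 500,
    address_reuse: float = 0.6,
    owner_autocorr: float = 0.5,
    split_prob: float = 0.2,
    section_area_km2: float = 2.59,
    crs: str = DEFAULT_CRS,
) -> ParcelSet:
    """Checkerboard section tenure with spatially autocorrelated ownership.

    Some private sections are split into four quarter-section parcels that
    share a mailing address with probability ``address_reuse``.
    """
    mix = agency_mix or DEFAULT_AGENCY_MIX
    probs = np.array(list(mix.values()), dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("agency_mix must be non-negative and sum to 1")
    agencies = list(mix.keys())
    rng = np.random.default_rng(seed)
    side = section_side(section_area_km2)
    nx, ny = _grid_shape(extent, side)
    xmin, ymin = extent[0], extent[1]

    agency_grid = {}
    owner_grid = {}
    for j in range(ny):
        for i in range(nx):
            agency = agencies[rng.choice(len(agencies), p=probs)]
            agency_grid[i, j] = agency
            owner = None
            for ni, nj in ((i - 1, j), (i, j - 1)):
                if (agency_grid.get((ni, nj)) == agency
                        and rng.random() < owner_autocorr):
                    owner = owner_grid[ni, nj]
                    break
            if owner is None:
                owner = f"owner_{int(rng.integers(owner_pool))}"
            owner_grid[i, j] = owner

    # shared edge coordinates must be bit-identical between neighbouring
    # sections or the boundary union keeps near-duplicate line-work
    xs = [xmin + i * side / 2.0 for i in range(2 * nx + 1)]
    ys = [ymin + j * side / 2.0 for j in range(2 * ny + 1)]

    parcels: list[Parcel] = []
    for j in range(ny):
        for i in range(nx):
            agency = agency_grid[i, j]
            owner = owner_grid[i, j]
            if agency == "private" and rng.random() < split_prob:
                shared = f"addr_{owner}" if rng.random() < address_reuse else None
                for qj in range(2):
                    for qi in range(2):
                        geom = box(xs[2 * i + qi], ys[2 * j + qj],
                                   xs[2 * i + qi + 1], ys[2 * j + qj + 1])
                        q_owner = f"{owner}_q{qi}{qj}"
                        address = shared if shared is not None else f"addr_{q_owner}"
                        parcels.append(Parcel(
                            geometry=geom, agency="private", owner_id=q_owner,
                            mailing_address=address, fid=len(parcels)))
            else:
                address = None if rng.random() < 0.1 else f"addr_{owner}"
                parcels.append(Parcel(
                    geometry=box(xs[2 * i], ys[2 * j], xs[2 * i + 2], ys[2 * j + 2]),
                    agency=agency,
                    owner_id=owner, mailing_address=address, fid=len(parcels)))
    return ParcelSet(parcels, crs)


def generate_pastures(tenure: ParcelSet, seed: int) -> ParcelSet:
    """Split each BLM parcel into 1-3 pasture strips that tile it exactly."""
    rng = np.random.default_rng(seed)
    pastures: list[Parcel] = []
    for p in tenure.by_agency("blm"):
        n_strips = int(rng.integers(1, 4))
        xmin, ymin, xmax, ymax = p.geometry.bounds
        cuts = np.sort(rng.uniform(0.25, 0.75, size=n_strips - 1)) if n_strips > 1 else []
        edges = [xmin] + [xmin + c * (xmax - xmin) for c in cuts] + [xmax]
        for k in range(len(edges) - 1):
            strip = box(edges[k], ymin, edges[k + 1], ymax).intersection(p.geometry)
            if not strip.is_empty and strip.area > 0:
                pastures.append(Parcel(
                    geometry=strip, agency="blm", owner_id="BLM",
                    mailing_address=None, fid=len(pastures)))
    return ParcelSet(pastures, tenure.crs)


# ---------------------------------------------------------------------------
# roads
# ---------------------------------------------------------------------------

def generate_roads(
    extent,
    seed: int,
    spacing: float | None = None,
    class_mix: dict[str, float] | None = None,
    line_offset: float = 55.0,
    jitter: float = 2.0,
    attached_stub_prob: float = 0.15,
    isolated_stub_prob: float = 0.12,
    section_area_km2: float = 2.59,
    crs: str = DEFAULT_CRS,
) -> RoadNetwork:
    """Grid roads parallel to section lines plus local stubs.

    Grid lines sit ``line_offset`` metres inside the section line (so road
    fences never coincide with parcel fences).  Attached stubs (< the long
    local threshold) hang perpendicularly off local grid roads; isolated
    stubs sit in section interiors, touching nothing.
    """
    mix = class_mix or DEFAULT_CLASS_MIX
    probs = np.array(list(mix.values()), dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be non-negative and sum to 1")
    classes = list(mix.keys())
    rng = np.random.default_rng(seed)
    side = section_side(section_area_km2)
    spacing = spacing or side
    xmin, ymin, xmax, ymax = extent
    roads: list[Road] = []

    def add(geom: LineString, road_class: str) -> None:
        roads.append(Road(geometry=geom, road_class=road_class, fid=len(roads)))

    vertical_locals: list[float] = []
    horizontal_locals: list[float] = []
    k = 0
    while xmin + k * spacing + line_offset < xmax:
        x = xmin + k * spacing + line_offset + rng.uniform(-jitter, jitter)
        cls = classes[rng.choice(len(classes), p=probs)]
        add(LineString([(x, ymin), (x, ymax)]), cls)
        if cls == "local":
            vertical_locals.append(x)
        k += 1
    k = 0
    while ymin + k * spacing + line_offset < ymax:
        y = ymin + k * spacing + line_offset + rng.uniform(-jitter, jitter)
        cls = classes[rng.choice(len(classes), p=probs)]
        add(LineString([(xmin, y), (xmax, y)]), cls)
        if cls == "local":
            horizontal_locals.append(y)
        k += 1

    # attached stubs: perpendicular, pointing into the section interior
    for x in vertical_locals:
        for j in range(int((ymax - ymin) / spacing)):
            if rng.random() < attached_stub_prob:
                y = ymin + (j + 0.5) * spacing
                length = rng.uniform(250.0, 600.0)
                if x + length < xmax:
                    add(LineString([(x, y), (x + length, y)]), "local")
    for y in horizontal_locals:
        for i in range(int((xmax - xmin) / spacing)):
            if rng.random() < attached_stub_prob:
                x = xmin + (i + 0.5) * spacing
                length = rng.uniform(250.0, 600.0)
                if y + length < ymax:
                    add(LineString([(x, y), (x, y + length)]), "local")

    # isolated stubs: diagonal, deep inside sections, far from all fences
    nx, ny = _grid_shape(extent, side)
    for j in range(ny):
        for i in range(nx):
            if rng.random() < isolated_stub_prob:
                cx = xmin + (i + 0.75) * side
                cy = ymin + (j + 0.75) * side
                half = rng.uniform(150.0, 200.0) / math.sqrt(2.0)
                add(LineString([(cx - half, cy - half), (cx + half, cy + half)]), "local")
    return RoadNetwork(roads, crs)


# ---------------------------------------------------------------------------
# land cover
# ---------------------------------------------------------------------------

def generate_landcover(
    extent,
    seed: int,
    crop_fraction: float = 0.35,
    hole_prob: float = 0.25,
    water_prob: float = 0.03,
    section_area_km2: float = 2.59,
    crs: str = DEFAULT_CRS,
) -> LandCoverMap:
    """Section-aligned crop/grassland/shrubland/mixed mosaic.

    Small grassland holes (well below half a section) are cut into some
    interior crop sections; a few water squares sit inside non-crop
    sections.
    """
    if not 0.0 <= crop_fraction <= 1.0:
        raise ValueError("crop_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    side = section_side(section_area_km2)
    nx, ny = _grid_shape(extent, side)
    xmin, ymin = extent[0], extent[1]

    classes = np.empty((nx, ny), dtype=object)
    for j in range(ny):
        for i in range(nx):
            if rng.random() < crop_fraction:
                classes[i, j] = "crop"
            else:
                classes[i, j] = ["grassland", "shrubland", "mixed"][
                    rng.choice(3, p=[0.6, 0.25, 0.15])]

    xs = [xmin + i * side for i in range(nx + 1)]
    ys = [ymin + j * side for j in range(ny + 1)]

    def cell(i, j):
        # bit-identical shared edges (see generate_tenure)
        return box(xs[i], ys[j], xs[i + 1], ys[j + 1])

    holes: list[Polygon] = []
    waters: list[Polygon] = []
    for j in range(ny):
        for i in range(nx):
            cx = xmin + (i + 0.5) * side
            cy = ymin + (j + 0.5) * side
            if classes[i, j] == "crop":
                neighbours_crop = all(
                    0 <= i + di < nx and 0 <= j + dj < ny and classes[i + di, j + dj] == "crop"
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)))
                if neighbours_crop and rng.random() < hole_prob:
                    h = 350.0  # 0.49 km², safely below half a section
                    holes.append(box(cx - h, cy - h, cx + h, cy + h))
            elif rng.random() < water_prob:
                w = 250.0
                waters.append(box(cx - w, cy - w, cx + w, cy + w))

    features: list[CoverPatch] = []
    for cover_class in ("crop", "grassland", "shrubland", "mixed"):
        geoms = [cell(i, j) for j in range(ny) for i in range(nx)
                 if classes[i, j] == cover_class]
        if not geoms:
            continue
        merged = shapely.union_all(geoms)
        if cover_class == "crop" and holes:
            merged = merged.difference(shapely.union_all(holes))
        if cover_class == "grassland":
            merged = shapely.union_all([merged] + holes) if holes else merged
        if waters:
            merged = merged.difference(shapely.union_all(waters))
        from .geo_core.layers import iter_polygons
        for part in iter_polygons(merged):
            features.append(CoverPatch(geometry=part, cover_class=cover_class,
                                       fid=len(features)))
    for w in waters:
        features.append(CoverPatch(geometry=w, cover_class="water", fid=len(features)))
    return LandCoverMap(features, crs)


def make_study_area(extent, margin: float = 100.0) -> Polygon:
    """Study-area polygon slightly larger than the fence extent, so interior
    fences are never mistaken for study-boundary artefacts."""
    xmin, ymin, xmax, ymax = extent
    return box(xmin - margin, ymin - margin, xmax + margin, ymax + margin)


# ---------------------------------------------------------------------------
# pipeline + truth
# ---------------------------------------------------------------------------

def run_pipeline(
    tenure: ParcelSet,
    pastures: ParcelSet | None,
    roads: RoadNetwork,
    landcover: LandCoverMap,
    config: ModelConfig,
    ledger: TenureRuleLedger | None = None,
    study_area: Polygon | None = None,
    exclusion_mask=None,
    provided: FenceLayer | None = None,
) -> dict:
    """Run the complete fence model; returns all intermediate layers."""
    tenure_fences = build_tenure_fences(tenure, pastures, config, ledger)
    lc_fences, masked_tenure, large_crop = build_landcover_fences(
        landcover, tenure_fences, config)
    road_layer = build_road_fences(roads, config, exclusion_mask)
    water_geoms = [c.geometry for c in landcover.by_class("water")]
    water = shapely.union_all(water_geoms) if water_geoms else None
    fences = synthesize(
        masked_tenure, lc_fences, road_layer, provided=provided, water=water,
        study_area=study_area, exclusion_mask=exclusion_mask, config=config)
    return {
        "tenure_fences": tenure_fences,
        "landcover_fences": lc_fences,
        "masked_tenure": masked_tenure,
        "large_crop": large_crop,
        "road_fences": road_layer,
        "fences": fences,
    }


def perturb_fences(
    fences: FenceLayer, seed: int, drop_prob: float = 0.0, jitter_sd: float = 0.0
) -> FenceLayer:
    """Randomly drop features and jitter vertices.

    The unit jitter field is drawn independently of ``jitter_sd`` and scaled
    by it, so at a fixed seed displacement grows monotonically with the sd.
    """
    drop_rng = np.random.default_rng([seed, 0])
    jitter_rng = np.random.default_rng([seed, 1])
    feats: list[Fence] = []
    for f in fences.features:
        coords = np.asarray(f.geometry.coords, dtype=float)
        unit = jitter_rng.standard_normal(coords.shape)
        dropped = drop_rng.random() < drop_prob
        if dropped:
            continue
        if jitter_sd > 0:
            coords = coords + jitter_sd * unit
        feats.append(Fence(LineString(coords), source=f.source, fid=len(feats)))
    return FenceLayer(feats, fences.crs)


def ground_truth_fences(
    tenure: ParcelSet,
    roads: RoadNetwork,
    landcover: LandCoverMap,
    config: ModelConfig,
    seed: int,
    perturbation: tuple[float, float] = (0.0, 0.0),
    pastures: ParcelSet | None = None,
    ledger: TenureRuleLedger | None = None,
    study_area: Polygon | None = None,
) -> FenceLayer:
    """Truth = the model's own output, optionally degraded.

    With zero perturbation the truth is exactly the model output, giving a
    controllable kappa dial for recovery tests.
    """
    layers = run_pipeline(tenure, pastures, roads, landcover, config,
                          ledger=ledger, study_area=study_area)
    drop_prob, jitter_sd = perturbation
    return perturb_fences(layers["fences"], seed, drop_prob, jitter_sd)


def design_survey_transects(
    roads: RoadNetwork,
    landcover: LandCoverMap,
    config: ModelConfig,
    seed: int,
    n_per_stratum: int = 4,
    n_controls: int = 4,
) -> list[Transect]:
    """Stratified transects plus control transects on isolated local roads.

    Length-weighted sampling almost never lands on the short isolated stubs,
    so a second draw restricted to locals disconnected from the fenced local
    network guarantees some transects without roadside fencing.
    """
    from .road_fences import classify_fenced_local_roads
    from .survey_accuracy import generate_transects, stratify_frame

    frame = stratify_frame(landcover, roads, config)
    transects = generate_transects(frame, n_per_stratum, config, seed)
    fenced_locals = classify_fenced_local_roads(roads, config)
    fenced_union = shapely.union_all([r.geometry for r in fenced_locals.features]) \
        if len(fenced_locals) else None
    control_frame = [
        s for s in frame
        if s.road_class == "local"
        and (fenced_union is None or s.geometry.distance(fenced_union) > 1.0)
    ]
    if control_frame:
        controls = generate_transects(control_frame, n_controls, config, seed + 1)
        offset = max((t.id for t in transects), default=-1) + 1
        for t in controls:
            t.id += offset
        transects = transects + controls
    return transects


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------

def simulate_survey(
    truth: FenceLayer,
    transects: list[Transect],
    detect_prob: float = 1.0,
    gps_sd_m: float = 0.0,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> tuple[list[SurveyPoint], list[Transect]]:
    """Simulate the roadside GPS survey against a truth fence layer.

    A transect observes fencing when a roadside (road-source) truth fence
    lies within the roadside distance of its line.  Events: endpoints of
    truth features inside the 200 m corridor (fence start/end) and crossing
    points of non-road truth fences with the transect line (interior fence
    meets road).  Events of the same type closer than the minimum structure
    length are merged (first kept); each event is detected with
    ``detect_prob`` and displaced by isotropic Gaussian GPS noise.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    geoms = truth.geometries()
    sources = [f.source for f in truth.features]
    tree = STRtree(geoms) if geoms else None

    points: list[SurveyPoint] = []
    labelled: list[Transect] = []
    for t in transects:
        line = t.geometry
        corridor = line.buffer(config.roadside_max_dist)
        nearby = tree.query(corridor, predicate="intersects").tolist() if tree else []
        fenced = any(
            sources[i] == "road"
            and geoms[i].distance(line) <= config.roadside_max_dist
            for i in nearby)
        labelled.append(replace(t, fenced_observed=fenced))

        events: list[tuple[str, Point]] = []
        for i in nearby:
            geom = geoms[i]
            start, end = Point(geom.coords[0]), Point(geom.coords[-1])
            if corridor.covers(start):
                events.append(("fence_start", start))
            if corridor.covers(end):
                events.append(("fence_end", end))
            if sources[i] != "road":
                crossing = geom.intersection(line)
                for pt in _as_points(crossing):
                    events.append(("interior_intersection", pt))
        events.sort(key=lambda e: (e[0], e[1].x, e[1].y))
        kept: list[tuple[str, Point]] = []
        for event, pt in events:
            if any(event == k_event and pt.distance(k_pt) < config.min_structure_change_len
                   for k_event, k_pt in kept):
                continue
            kept.append((event, pt))
        for event, pt in kept:
            if rng.random() >= detect_prob:
                continue
            if gps_sd_m > 0:
                dx, dy = rng.standard_normal(2) * gps_sd_m
                pt = Point(pt.x + dx, pt.y + dy)
            points.append(SurveyPoint(
                location=pt, transect_id=t.id, event=event,
                on_fenced_transect=fenced))
    log.info("survey: %d points on %d transects (%d fenced)",
             len(points), len(transects),
             sum(1 for t in labelled if t.fenced_observed))
    return points, labelled


def _as_points(geom):
    if geom.is_empty:
        return
    if geom.geom_type == "Point":
        yield geom
    elif hasattr(geom, "geoms"):
        for g in geom.geoms:
            yield from _as_points(g)
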