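"""Survey design and buffered-point accuracy assessment.

Transects are random road segments stratified by habitat x pavement; model
accuracy is scored by three confusion constructions (roads-only, internal
fencing, total) against surveyed points, followed by Cohen's kappa with an
asymptotic standard error and normal 95% interval.

Matching semantics: a reference point buffered by the spatial-error radius
matches a modeled fence line when the point lies within that radius of the
line; two buffered points match when their centres are within twice the
radius (disk overlap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely import STRtree
from shapely.geometry import LineString, Point
from shapely.ops import substring

from .geo_core import FenceLayer, LandCoverMap, ModelConfig, RoadNetwork
from .geo_core.errors import DegenerateMarginalsError

log = logging.getLogger(__name__)

HABITATS = ("Grass", "Agriculture", "Shrub", "Mix")
PAVEMENTS = ("Paved", "Unpaved")
STRATA = tuple(f"{h}/{p}" for h in HABITATS for p in PAVEMENTS)

EVENTS = frozenset({"fence_start", "fence_end", "structure_change", "interior_intersection"})

#: habitat label per land-cover class; anything else falls into Mix
HABITAT_BY_COVER = {"grassland": "Grass", "crop": "Agriculture", "shrubland": "Shrub",
                    "mixed": "Mix"}


@dataclass
class Transect:
    id: int
    midpoint: Point
    geometry: LineString
    length: float
    stratum: str
    fenced_observed: bool | None = None


@dataclass
class SurveyPoint:
    location: Point
    transect_id: int
    event: str
    on_fenced_transect: bool = False

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValueError(f"unknown event {self.event!r}")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class StratifiedSegment:
    geometry: LineString
    stratum: str
    road_class: str


# ---------------------------------------------------------------------------
# survey frame and transects
# ---------------------------------------------------------------------------

def stratify_frame(
    landcover: LandCoverMap, roads: RoadNetwork, config: ModelConfig | None = None
) -> list[StratifiedSegment]:
    """Split roads at habitat boundaries and tag each piece with its stratum."""
    config = config or ModelConfig()
    regions = {}
    for cover_class, habitat in HABITAT_BY_COVER.items():
        geoms = [c.geometry for c in landcover.by_class(cover_class)]
        if geoms:
            prev = regions.get(habitat)
            merged = shapely.union_all(geoms + ([prev] if prev is not None else []))
            regions[habitat] = merged
    segments: list[StratifiedSegment] = []
    for road in roads.features:
        if road.road_class in config.paved_classes:
            pavement = "Paved"
        elif road.road_class in ("local",):
            pavement = "Unpaved"
        else:  # pragma: no cover - closed enum today, guard for config edits
            log.info("road %d has unknown pavement status; excluded", road.fid)
            continue
        remaining = road.geometry
        for habitat in ("Grass", "Agriculture", "Shrub"):
            region = regions.get(habitat)
            if region is None or remaining.is_empty:
                continue
            inside = remaining.intersection(region)
            remaining = remaining.difference(region)
            for line in _lines_of(inside):
                segments.append(StratifiedSegment(line, f"{habitat}/{pavement}", road.road_class))
        for line in _lines_of(remaining):
            segments.append(StratifiedSegment(line, f"Mix/{pavement}", road.road_class))
    return [s for s in segments if s.geometry.length > 1.0]


def _lines_of(geom):
    from .geo_core.layers import iter_lines
    return list(iter_lines(geom))


def generate_transects(
    frame: list[StratifiedSegment],
    n_per_stratum: int,
    config: ModelConfig,
    seed: int,
) -> list[Transect]:
    """Seeded random transect midpoints per stratum with global minimum spacing.

    Each transect is traced half the transect length in both directions along
    its road segment, truncated at segment ends.
    """
    if n_per_stratum < 0:
        raise ValueError("n_per_stratum must be >= 0")
    rng = np.random.default_rng(seed)
    accepted: list[Transect] = []
    half = config.transect_length / 2.0
    for stratum in STRATA:
        segs = [s for s in frame if s.stratum == stratum]
        if not segs or n_per_stratum == 0:
            continue
        lengths = np.array([s.geometry.length for s in segs])
        weights = lengths / lengths.sum()
        count = 0
        for _ in range(max(200, 200 * n_per_stratum)):
            if count >= n_per_stratum:
                break
            seg = segs[rng.choice(len(segs), p=weights)]
            d = rng.uniform(0.0, seg.geometry.length)
            midpoint = seg.geometry.interpolate(d)
            if any(midpoint.distance(t.midpoint) < config.transect_min_spacing
                   for t in accepted):
                continue
            lo, hi = max(0.0, d - half), min(seg.geometry.length, d + half)
            geom = substring(seg.geometry, lo, hi)
            if geom.length < hi - lo - config.length_tolerance:  # pragma: no cover
                continue
            if geom.length < config.transect_length - config.length_tolerance:
                log.info("transect %d truncated to %.0f m at segment end",
                         len(accepted), geom.length)
            accepted.append(Transect(
                id=len(accepted), midpoint=midpoint, geometry=geom,
                length=geom.length, stratum=stratum))
            count += 1
        if count < n_per_stratum:
            log.warning("stratum %s: only %d of %d transects placed",
                        stratum, count, n_per_stratum)
    return accepted


def densify_to_points(line: LineString, interval: float) -> list[Point]:
    """Points along a line every ``interval`` metres, endpoints included."""
    distances = np.arange(0.0, line.length, interval).tolist()
    if not distances or line.length - distances[-1] > 1e-9:
        distances.append(line.length)
    return [line.interpolate(d) for d in distances]


# ---------------------------------------------------------------------------
# confusion constructions
# ---------------------------------------------------------------------------

def _count_near_lines(points: list[Point], lines: list[LineString], radius: float) -> int:
    if not points or not lines:
        return 0
    tree = STRtree(lines)
    count = 0
    for pt in points:
        idx = tree.query(pt.buffer(radius), predicate="intersects")
        if any(pt.distance(lines[i]) <= radius for i in idx):
            count += 1
    return count


def roads_confusion(
    fenced_transects: list[Transect],
    nonfenced_transects: list[Transect],
    modeled_road_fences: FenceLayer,
    config: ModelConfig,
) -> ConfusionCounts:
    """Roads-only assessment: densified transect points vs road fences."""
    if not fenced_transects or not nonfenced_transects:
        raise ValueError("both fenced and non-fenced transects are required")
    lines = modeled_road_fences.geometries()
    pos_points = [p for t in fenced_transects
                  for p in densify_to_points(t.geometry, config.densify_interval)]
    neg_points = [p for t in nonfenced_transects
                  for p in densify_to_points(t.geometry, config.densify_interval)]
    tp = _count_near_lines(pos_points, lines, config.accuracy_buffer)
    fp = _count_near_lines(neg_points, lines, config.accuracy_buffer)
    return ConfusionCounts(tp=tp, fp=fp, fn=len(pos_points) - tp,
                           tn=len(neg_points) - fp)


def internal_intersection_nodes(
    internal: FenceLayer, bend_threshold_deg: float = 45.0
) -> list[Point]:
    """Junction points of the internal fencing.

    Includes pairwise feature intersections and sharp interior bends (a
    corner where two fence courses meet is a junction even when line
    merging stitched them into one feature).
    """
    geoms = internal.geometries()
    if not geoms:
        return []
    nodes: list[Point] = []
    seen = set()

    def add(pt: Point) -> None:
        key = (round(pt.x, 3), round(pt.y, 3))
        if key not in seen:
            seen.add(key)
            nodes.append(pt)

    if len(geoms) > 1:
        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        for i, j in zip(left.tolist(), right.tolist()):
            if i < j:
                for pt in _points_of(geoms[i].intersection(geoms[j])):
                    add(pt)
    cos_limit = math.cos(math.radians(bend_threshold_deg))
    for geom in geoms:
        coords = np.asarray(geom.coords, dtype=float)
        for k in range(1, len(coords) - 1):
            v1 = coords[k] - coords[k - 1]
            v2 = coords[k + 1] - coords[k]
            n1, n2 = np.hypot(*v1), np.hypot(*v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            if float(v1 @ v2) / (n1 * n2) < cos_limit:
                add(Point(coords[k]))
    return nodes


def _points_of(geom):
    if geom.is_empty:
        return
    if geom.geom_type == "Point":
        yield geom
    elif geom.geom_type in ("MultiPoint", "GeometryCollection"):
        for g in geom.geoms:
            yield from _points_of(g)
    elif geom.geom_type in ("LineString", "MultiLineString"):
        # collinear overlap: its endpoints are junctions of the two features
        for line in _lines_of(geom):
            yield Point(line.coords[0])
            yield Point(line.coords[-1])


def _random_points_on_transects(
    transects: list[Transect],
    n: int,
    rng: np.random.Generator,
    keepout: list[Point] | None = None,
    keepout_radius: float = 0.0,
) -> list[Point]:
    lengths = np.array([t.geometry.length for t in transects], dtype=float)
    weights = lengths / lengths.sum()
    keepout_tree = STRtree(keepout) if keepout else None
    points: list[Point] = []
    attempts = 0
    while len(points) < n and attempts < 50 * max(n, 1):
        attempts += 1
        t = transects[rng.choice(len(transects), p=weights)]
        pt = t.geometry.interpolate(rng.uniform(0.0, t.geometry.length))
        if keepout_tree is not None:
            idx = keepout_tree.query(pt.buffer(keepout_radius))
            if any(pt.distance(keepout[i]) < keepout_radius for i in idx):
                continue
        points.append(pt)
    if len(points) < n:
        log.warning("placed only %d of %d random points", len(points), n)
    return points


def internal_confusion(
    survey_points: list[SurveyPoint],
    modeled_fences: FenceLayer,
    modeled_road_fences: FenceLayer,
    fenced_transects: list[Transect],
    config: ModelConfig,
    seed: int,
    literal_fp: bool = False,
) -> ConfusionCounts:
    """Internal-fencing assessment.

    The internal model is the modeled fencing minus road fencing; its
    feature-intersection nodes, buffered by the error radius, are matched
    against buffered survey points (disk overlap).  Negatives are seeded
    random points on fenced transects away from survey points, scored
    against the internal fence lines.

    By default the unmatched survey points are false negatives (consistent
    with the other assessments); ``literal_fp=True`` reproduces the variant
    arithmetic in which that difference is reported as false positives.
    """
    if not survey_points:
        raise ValueError("survey points are required")
    if not fenced_transects:
        raise ValueError("fenced transects are required")
    internal = modeled_fences.by_source("tenure", "landcover", "provided")
    nodes = internal_intersection_nodes(internal)
    if not nodes:
        log.info("internal model has no intersection nodes; tp = 0")
    node_tree = STRtree(nodes) if nodes else None
    match_dist = 2 * config.accuracy_buffer
    tp = 0
    for sp in survey_points:
        if node_tree is None:
            break
        idx = node_tree.query(sp.location.buffer(match_dist))
        if any(sp.location.distance(nodes[i]) <= match_dist for i in idx):
            tp += 1
    miss = len(survey_points) - tp

    rng = np.random.default_rng(seed)
    n_random = int(round(config.negatives_per_positive * len(survey_points)))
    randoms = _random_points_on_transects(
        fenced_transects, n_random, rng,
        keepout=[sp.location for sp in survey_points],
        keepout_radius=config.accuracy_buffer)
    fp = _count_near_lines(randoms, internal.geometries(), config.accuracy_buffer)
    tn = len(randoms) - fp
    if literal_fp:
        return ConfusionCounts(tp=tp, fp=miss, fn=fp, tn=tn)
    return ConfusionCounts(tp=tp, fp=fp, fn=miss, tn=tn)


def total_confusion(
    survey_points: list[SurveyPoint],
    modeled_fences: FenceLayer,
    nonfenced_transects: list[Transect],
    config: ModelConfig,
    seed: int,
) -> ConfusionCounts:
    """Total assessment: all survey points vs the complete modeled layer."""
    if not survey_points:
        raise ValueError("survey points are required")
    if not nonfenced_transects:
        raise ValueError("non-fenced transects are required")
    lines = modeled_fences.geometries()
    tp = _count_near_lines([sp.location for sp in survey_points], lines,
                           config.accuracy_buffer)
    rng = np.random.default_rng(seed)
    n_random = int(round(config.negatives_per_positive * len(survey_points)))
    randoms = _random_points_on_transects(
        nonfenced_transects, n_random, rng,
        keepout=[sp.location for sp in survey_points],
        keepout_radius=config.accuracy_buffer)
    fp = _count_near_lines(randoms, lines, config.accuracy_buffer)
    return ConfusionCounts(tp=tp, fp=fp, fn=len(survey_points) - tp,
                           tn=len(randoms) - fp)


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    total_accuracy: float
    p_o: float
    p_e: float


def cohens_kappa(c: ConfusionCounts) -> KappaResult:
    """Chance-corrected agreement for a 2x2 confusion table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed accuracy and p_e
    the chance agreement from the marginals.  The standard error is the
    large-sample form of Fleiss, Cohen & Everitt (1969) and the interval is
    a normal 95% CI.
    """
    n = c.n
    if n <= 0:
        raise ValueError("confusion table is empty")
    p = np.array([[c.tp, c.fn], [c.fp, c.tn]], dtype=float) / n
    p_o = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-15:
        raise DegenerateMarginalsError("chance agreement equals 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2))
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j)
    cterm = (kappa - p_e * (1.0 - kappa)) ** 2
    var = max(0.0, (a + b - cterm) / (n * (1.0 - p_e) ** 2))
    se = math.sqrt(var)
    z = 1.959963984540054
    return KappaResult(
        kappa=float(kappa), se=float(se),
        ci95=(float(kappa - z * se), float(kappa + z * se)),
        total_accuracy=float(p_o), p_o=float(p_o), p_e=float(p_e))
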