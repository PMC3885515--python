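"""Land-tenure fence rules.

Transforms a raw parcel layer into merged fencing units by applying, in a
fixed order, a ledger of ownership/adjacency assumptions, then emits the
deduplicated outlines of the resulting units as tenure fences.

Adjacency throughout means a shared boundary of positive length: parcels
touching only at a corner are *not* adjacent (a point contact cannot omit a
fence segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import shapely
from shapely import STRtree

from .geo_core import FenceLayer, ModelConfig, Parcel, ParcelSet, UNFENCED_AGENCIES
from .geo_core.outlines import polygon_outlines

log = logging.getLogger(__name__)

#: execution order of the tenure rules
RULE_ORDER = (
    "substitute_blm_pastures",
    "dissolve_state",
    "absorb_state_into_blm",
    "dissolve_bor",
    "dissolve_fws",
    "merge_private_tribal",
    "drop_nps_usfs",
    "township",  # reserved slot, disabled: semantics undefined by the source rules
)


@dataclass
class TenureRule:
    rule_id: str
    enabled: bool = True


@dataclass
class TenureRuleLedger:
    """Ordered, toggleable record of the tenure rules.

    Rules may be disabled but not reordered; unknown rule ids are rejected.
    """

    rules: list[TenureRule] = field(default_factory=lambda: [
        TenureRule(rid, enabled=(rid != "township")) for rid in RULE_ORDER
    ])

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rule ids in ledger")
        unknown = set(ids) - set(RULE_ORDER)
        if unknown:
            raise ValueError(f"unknown rule ids: {sorted(unknown)}")

    def enabled(self, rule_id: str) -> bool:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r.enabled
        return False

    def disable(self, *rule_ids: str) -> "TenureRuleLedger":
        return TenureRuleLedger([
            TenureRule(r.rule_id, r.enabled and r.rule_id not in rule_ids)
            for r in self.rules
        ])

    @classmethod
    def all_disabled(cls) -> "TenureRuleLedger":
        return cls([TenureRule(rid, enabled=False) for rid in RULE_ORDER])


# ---------------------------------------------------------------------------
# adjacency helpers
# ---------------------------------------------------------------------------

def shared_boundary_length(a, b) -> float:
    inter = a.intersection(b)
    return inter.length if not inter.is_empty else 0.0


def _adjacency_pairs(geoms: list) -> list[tuple[int, int]]:
    """Index pairs of polygons sharing a boundary of positive length."""
    if len(geoms) < 2:
        return []
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    pairs = []
    for i, j in zip(left.tolist(), right.tolist()):
        if i < j and shared_boundary_length(geoms[i], geoms[j]) > 0:
            pairs.append((i, j))
    return pairs


def _renumber(parcels: list[Parcel]) -> list[Parcel]:
    return [replace(p, fid=i) for i, p in enumerate(parcels)]


def _merge_group(members: list[Parcel]) -> Parcel:
    lead = min(members, key=lambda p: p.fid)
    geom = shapely.union_all([p.geometry for p in members])
    return Parcel(
        geometry=geom, agency=lead.agency, owner_id=lead.owner_id,
        mailing_address=lead.mailing_address, area=geom.area / 1e6, fid=lead.fid,
        fenced=lead.fenced)


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

def substitute_blm_pastures(tenure: ParcelSet, pastures: ParcelSet) -> ParcelSet:
    """Replace BLM parcels with BLM pasture polygons.

    Pasture outlines become the only fences on BLM land.  Pastures are
    clipped to the BLM footprint; any BLM area the pastures do not cover is
    retained as BLM parcels so no landscape area is lost.
    """
    blm = tenure.by_agency("blm")
    others = [p for p in tenure.features if p.agency != "blm"]
    if not blm:
        return tenure.copy()
    if not len(pastures):
        log.warning("no pastures supplied; %d BLM parcels passed through", len(blm))
        return tenure.copy()
    footprint = shapely.union_all([p.geometry for p in blm])
    out = [replace(p) for p in others]
    covered = []
    for pas in pastures.features:
        clipped = pas.geometry.intersection(footprint)
        if clipped.is_empty or clipped.area <= 0:
            continue
        if clipped.area < pas.geometry.area - 1e-9:
            log.info("pasture %d clipped to BLM footprint", pas.fid)
        out.append(Parcel(geometry=clipped, agency="blm", owner_id=pas.owner_id,
                          mailing_address=None, area=clipped.area / 1e6))
        covered.append(clipped)
    uncovered = footprint.difference(shapely.union_all(covered)) if covered else footprint
    if uncovered.area > 1e-6:
        log.warning("pastures leave %.4f km2 of BLM uncovered; retained as BLM",
                    uncovered.area / 1e6)
        out.append(Parcel(geometry=uncovered, agency="blm", owner_id=None,
                          mailing_address=None, area=uncovered.area / 1e6))
    return ParcelSet(_renumber(out), tenure.crs)


def dissolve_adjacent_same_agency(parcels: ParcelSet, agency: str) -> ParcelSet:
    """Merge every maximal edge-adjacent group of parcels of one agency."""
    if agency not in ("state", "bor", "fws"):
        raise ValueError(f"dissolve rule applies to state/bor/fws, not {agency!r}")
    target = [p for p in parcels.features if p.agency == agency]
    rest = [replace(p) for p in parcels.features if p.agency != agency]
    if len(target) < 2:
        return parcels.copy()
    graph = nx.Graph()
    graph.add_nodes_from(range(len(target)))
    graph.add_edges_from(_adjacency_pairs([p.geometry for p in target]))
    merged = [
        _merge_group([target[i] for i in comp])
        for comp in nx.connected_components(graph)
    ]
    merged.sort(key=lambda p: p.fid)
    return ParcelSet(_renumber(rest + merged), parcels.crs)


def absorb_enclosed_state_into_blm(
    parcels: ParcelSet, tolerance: float = 0.01
) -> ParcelSet:
    """Dissolve state parcels whose entire boundary is shared with BLM land.

    A state parcel bordered by anything other than BLM on any stretch of its
    boundary is retained.  Absorbed parcels merge into the BLM neighbour with
    the longest shared boundary.
    """
    blm = [p for p in parcels.features if p.agency == "blm"]
    if not blm:
        return parcels.copy()
    blm_union = shapely.union_all([p.geometry for p in blm])
    out = []
    absorbed: dict[int, list[Parcel]] = {}
    for p in parcels.features:
        if p.agency != "state":
            out.append(replace(p))
            continue
        residual = p.geometry.boundary.difference(blm_union.boundary)
        if residual.length < tolerance:
            host = max(blm, key=lambda b: shared_boundary_length(b.geometry, p.geometry))
            absorbed.setdefault(host.fid, []).append(p)
            log.info("state parcel %d absorbed into BLM parcel %d", p.fid, host.fid)
        else:
            out.append(replace(p))
    if not absorbed:
        return ParcelSet(_renumber(out), parcels.crs)
    result = []
    for p in out:
        if p.agency == "blm" and p.fid in absorbed:
            geom = shapely.union_all([p.geometry] + [a.geometry for a in absorbed[p.fid]])
            result.append(replace(p, geometry=geom, area=geom.area / 1e6))
        else:
            result.append(p)
    return ParcelSet(_renumber(result), parcels.crs)


def merge_private_tribal(
    parcels: ParcelSet, config: ModelConfig
) -> tuple[ParcelSet, list[dict]]:
    """Merge private/tribal parcels into fencing units.

    Step 1: adjacent parcels with the same owner merge at any size; private
    parcels below half a section also merge on a shared, non-null mailing
    address.  Step 2: merged units larger than two sections stand as fencing
    units.  Step 3: each remaining small unit is dissolved into the adjacent
    unit whose area is closest to two sections (ties: longest shared
    boundary, then lowest id); isolated small units are kept and logged.

    Returns the new ParcelSet and an absorption report of
    ``{"small_id": ..., "host_id": ...}`` rows.
    """
    pt = [p for p in parcels.features if p.agency in ("private", "tribal")]
    rest = [replace(p) for p in parcels.features if p.agency not in ("private", "tribal")]
    if not pt:
        return parcels.copy(), []

    geoms = [p.geometry for p in pt]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(pt)))
    for i, j in _adjacency_pairs(geoms):
        a, b = pt[i], pt[j]
        same_owner = a.owner_id is not None and a.owner_id == b.owner_id
        address_match = (
            a.agency == "private" and b.agency == "private"
            and (a.area or 0) < config.half_section_area
            and (b.area or 0) < config.half_section_area
            and a.mailing_address is not None
            and a.mailing_address == b.mailing_address
        )
        if same_owner or address_match:
            graph.add_edge(i, j)
    units = [
        _merge_group([pt[i] for i in comp]) for comp in nx.connected_components(graph)
    ]
    units.sort(key=lambda p: p.fid)

    report: list[dict] = []
    # step 3: dissolve small units, smallest first, into the neighbour whose
    # area is nearest two sections
    while True:
        smalls = sorted(
            (u for u in units if u.area <= config.two_sections_area),
            key=lambda u: (u.area, u.fid))
        dissolved_any = False
        for small in smalls:
            hosts = [
                (u, shared_boundary_length(u.geometry, small.geometry))
                for u in units if u is not small
            ]
            hosts = [(u, shared) for u, shared in hosts if shared > 0]
            if not hosts:
                continue
            host, _ = min(
                hosts,
                key=lambda h: (abs(h[0].area - config.two_sections_area), -h[1], h[0].fid))
            geom = shapely.union_all([host.geometry, small.geometry])
            units = [u for u in units if u is not small and u is not host]
            units.append(replace(host, geometry=geom, area=geom.area / 1e6))
            units.sort(key=lambda p: p.fid)
            report.append({"small_id": small.fid, "host_id": host.fid})
            dissolved_any = True
            break
        if not dissolved_any:
            break
    for u in units:
        if u.area <= config.two_sections_area:
            log.info("small private/tribal unit %d kept (no adjacent unit)", u.fid)
    return ParcelSet(_renumber(rest + units), parcels.crs), report


def drop_unfenced_agencies(parcels: ParcelSet) -> ParcelSet:
    """Mark NPS and USFS land as unfenced.

    The parcels are retained (area bookkeeping) but contribute no outlines;
    a boundary against a fenced neighbour survives via that neighbour.
    """
    out = [
        replace(p, fenced=False) if p.agency in UNFENCED_AGENCIES else replace(p)
        for p in parcels.features
    ]
    return ParcelSet(out, parcels.crs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def apply_tenure_rules(
    tenure: ParcelSet,
    pastures: ParcelSet | None,
    config: ModelConfig,
    ledger: TenureRuleLedger | None = None,
) -> tuple[ParcelSet, list[dict]]:
    """Run the enabled tenure rules in ledger order; return parcels + report."""
    ledger = ledger or TenureRuleLedger()
    parcels = tenure.copy()
    report: list[dict] = []
    if ledger.enabled("substitute_blm_pastures"):
        parcels = substitute_blm_pastures(parcels, pastures or ParcelSet([], tenure.crs))
    if ledger.enabled("dissolve_state"):
        parcels = dissolve_adjacent_same_agency(parcels, "state")
    if ledger.enabled("absorb_state_into_blm"):
        parcels = absorb_enclosed_state_into_blm(parcels, config.length_tolerance)
    if ledger.enabled("dissolve_bor"):
        parcels = dissolve_adjacent_same_agency(parcels, "bor")
    if ledger.enabled("dissolve_fws"):
        parcels = dissolve_adjacent_same_agency(parcels, "fws")
    if ledger.enabled("merge_private_tribal"):
        parcels, report = merge_private_tribal(parcels, config)
    if ledger.enabled("drop_nps_usfs"):
        parcels = drop_unfenced_agencies(parcels)
    return parcels, report


def build_tenure_fences(
    tenure: ParcelSet,
    pastures: ParcelSet | None,
    config: ModelConfig,
    ledger: TenureRuleLedger | None = None,
) -> FenceLayer:
    """Apply the tenure rules and emit the resulting outlines as tenure fences."""
    parcels, _ = apply_tenure_rules(tenure, pastures, config, ledger)
    fences = polygon_outlines(parcels, source="tenure")
    log.info("tenure fences: %.2f km from %d units", fences.total_length, len(parcels))
    return fences
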