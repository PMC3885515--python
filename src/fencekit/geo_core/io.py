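"""Layer loading and saving.

Supported formats: GeoJSON (``.geojson``/``.json``) and GeoPackage
(``.gpkg``).  ESRI shapefile is recognised but rejected with a clear error —
no shapefile driver is available in this build.

All layers must declare a projected, metre-unit CRS.  GeoJSON files carry it
in a legacy ``crs`` member (``{"type": "name", "properties": {"name":
"EPSG:32613"}}``); GeoPackages in ``gpkg_spatial_ref_sys``.  Geographic CRSs
are rejected: every rule threshold in the model is metric.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from shapely.geometry import mapping, shape

from . import gpkg
from .errors import (
    EmptyLayerError,
    GeographicCRSError,
    MissingAttributeError,
    MissingFileError,
    UnknownCRSError,
    UnsupportedFormatError,
)
from .layers import (
    CoverPatch,
    Fence,
    FenceLayer,
    LandCoverMap,
    Parcel,
    ParcelSet,
    Road,
    RoadNetwork,
    iter_lines,
    repair_geometry,
)

log = logging.getLogger(__name__)

GEOGRAPHIC_CRS = {
    "EPSG:4326", "EPSG:4269", "EPSG:4267", "EPSG:4258",
    "OGC:CRS84", "CRS84", "WGS84", "URN:OGC:DEF:CRS:OGC:1.3:CRS84",
}

#: canonical attribute names per layer role; a field map may rename sources
ROLE_FIELDS = {
    "parcels": ("agency", "owner_id", "mailing_address", "area"),
    "roads": ("road_class", "length", "fenced_flag"),
    "landcover": ("cover_class",),
    "fences": ("source",),
}
REQUIRED_FIELDS = {
    "parcels": ("agency",),
    "roads": ("road_class",),
    "landcover": ("cover_class",),
    "fences": (),
}


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        return "geojson"
    if suffix == ".gpkg":
        return "gpkg"
    if suffix == ".shp":
        raise UnsupportedFormatError(
            f"{path}: shapefile I/O is not available in this build; "
            "use GeoJSON or GeoPackage")
    raise UnsupportedFormatError(f"{path}: unrecognised format {suffix!r}")


def _check_crs(crs: str | None, name: str) -> str:
    if not crs:
        raise UnknownCRSError(f"layer {name!r} has no CRS; a projected metric CRS is required")
    if crs.upper() in GEOGRAPHIC_CRS:
        raise GeographicCRSError(
            f"layer {name!r} is in geographic CRS {crs}; reproject to a metric CRS first")
    return crs


def _read_raw(path: Path):
    fmt = _detect_format(path)
    if fmt == "geojson":
        data = json.loads(path.read_text())
        crs = None
        if isinstance(data.get("crs"), dict):
            crs = data["crs"].get("properties", {}).get("name")
        geoms, props = [], []
        for feat in data.get("features", []):
            geoms.append(shape(feat["geometry"]))
            props.append(feat.get("properties") or {})
        return geoms, props, crs
    geoms, props, crs, _ = gpkg.read_table(path)
    return geoms, props, crs


def load_layer(
    path: str | Path,
    expected_role: str,
    field_map: dict[str, str] | None = None,
    crs_override: str | None = None,
):
    """Load and validate a typed layer.

    Parameters
    ----------
    expected_role : one of ``parcels``, ``roads``, ``landcover``, ``fences``.
    field_map : optional mapping from canonical attribute name to the source
        column name in the file.
    """
    path = Path(path)
    if expected_role not in ROLE_FIELDS:
        raise ValueError(f"unknown layer role {expected_role!r}")
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    geoms, props, crs = _read_raw(path)
    crs = _check_crs(crs_override or crs, path.name)
    if not geoms:
        raise EmptyLayerError(f"layer {path.name!r} has no features")

    fmap = {k: k for k in ROLE_FIELDS[expected_role]}
    fmap.update(field_map or {})
    for canonical in REQUIRED_FIELDS[expected_role]:
        source = fmap[canonical]
        if not any(source in p for p in props):
            raise MissingAttributeError(
                f"layer {path.name!r} is missing mapped attribute {source!r} "
                f"(for {canonical!r})")

    def get(p, canonical):
        return p.get(fmap[canonical])

    features = []
    if expected_role == "parcels":
        for i, (g, p) in enumerate(zip(geoms, props)):
            g = repair_geometry(g, f"{path.name}#{i}")
            features.append(Parcel(
                geometry=g, agency=get(p, "agency"), owner_id=get(p, "owner_id"),
                mailing_address=get(p, "mailing_address"),
                area=_opt_float(get(p, "area")), fid=i))
        layer = ParcelSet(features, crs)
    elif expected_role == "roads":
        for i, (g, p) in enumerate(zip(geoms, props)):
            for line in iter_lines(g):
                features.append(Road(
                    geometry=line, road_class=get(p, "road_class"),
                    length=_opt_float(get(p, "length")),
                    fenced_flag=_opt_bool(get(p, "fenced_flag")), fid=len(features)))
        layer = RoadNetwork(features, crs)
    elif expected_role == "landcover":
        for i, (g, p) in enumerate(zip(geoms, props)):
            g = repair_geometry(g, f"{path.name}#{i}")
            features.append(CoverPatch(geometry=g, cover_class=get(p, "cover_class"), fid=i))
        layer = LandCoverMap(features, crs)
    else:
        for i, (g, p) in enumerate(zip(geoms, props)):
            for line in iter_lines(g):
                features.append(Fence(
                    geometry=line, source=get(p, "source") or "provided",
                    fid=len(features)))
        layer = FenceLayer(features, crs)
    log.info("loaded %s: %d features from %s", expected_role, len(features), path)
    return layer


def _opt_float(v):
    return None if v is None else float(v)


def _opt_bool(v):
    if v is None:
        return None
    if isinstance(v, str):
        return v.lower() in ("1", "true", "t", "yes")
    return bool(v)


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def _layer_records(layer):
    if isinstance(layer, ParcelSet):
        return [(p.geometry, {
            "agency": p.agency, "owner_id": p.owner_id,
            "mailing_address": p.mailing_address, "area": p.area,
        }) for p in layer.features], "POLYGON"
    if isinstance(layer, RoadNetwork):
        return [(r.geometry, {
            "road_class": r.road_class, "length": r.length,
            "fenced_flag": r.fenced_flag,
        }) for r in layer.features], "LINESTRING"
    if isinstance(layer, LandCoverMap):
        return [(c.geometry, {"cover_class": c.cover_class}) for c in layer.features], "POLYGON"
    if isinstance(layer, FenceLayer):
        return [(f.geometry, {"source": f.source}) for f in layer.features], "LINESTRING"
    raise TypeError(f"cannot save object of type {type(layer).__name__}")


def save_layer(layer, path: str | Path, fmt: str | None = None) -> Path:
    """Write a typed layer; the format is inferred from the suffix unless given."""
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt not in ("geojson", "gpkg"):
        raise UnsupportedFormatError(f"unsupported output format {fmt!r}")
    records, geom_type = _layer_records(layer)
    if fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": layer.crs}},
            "features": [
                {"type": "Feature", "geometry": mapping(g), "properties": p}
                for g, p in records
            ],
        }
        path.write_text(json.dumps(doc))
    else:
        gpkg.write_table(
            path, path.stem, [g for g, _ in records], [p for _, p in records],
            layer.crs, geometry_type=geom_type)
    log.info("wrote %d features to %s", len(records), path)
    return path
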