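"""Minimal GeoPackage reader/writer built on sqlite3 + WKB.

Implements just enough of the OGC GeoPackage spec (feature tables,
``gpkg_contents``, ``gpkg_geometry_columns``, ``gpkg_spatial_ref_sys``, the
``GP`` geometry blob header) to round-trip this package's vector layers.
No spatial index, single geometry column named ``geom``.
"""

from __future__ import annotations

import sqlite3
import struct
from pathlib import Path

import shapely
from shapely.geometry.base import BaseGeometry

GPKG_APPLICATION_ID = 0x47504B47  # "GPKG"

_SRS_SETUP = """
CREATE TABLE IF NOT EXISTS gpkg_spatial_ref_sys (
  srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
  organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
  definition TEXT NOT NULL, description TEXT);
CREATE TABLE IF NOT EXISTS gpkg_contents (
  table_name TEXT PRIMARY KEY, data_type TEXT NOT NULL, identifier TEXT UNIQUE,
  description TEXT DEFAULT '', last_change DATETIME, min_x DOUBLE, min_y DOUBLE,
  max_x DOUBLE, max_y DOUBLE, srs_id INTEGER);
CREATE TABLE IF NOT EXISTS gpkg_geometry_columns (
  table_name TEXT NOT NULL, column_name TEXT NOT NULL,
  geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
  z TINYINT NOT NULL, m TINYINT NOT NULL,
  CONSTRAINT pk_geom_cols PRIMARY KEY (table_name, column_name));
"""


def _srs_id(crs: str | None) -> int:
    if crs and crs.upper().startswith("EPSG:"):
        return int(crs.split(":")[1])
    return 0


def encode_geometry(geom: BaseGeometry, srs_id: int) -> bytes:
    # header: magic, version, flags (little-endian byte order, no envelope)
    header = struct.pack("<2sBBi", b"GP", 0, 0b00000001, srs_id)
    return header + shapely.to_wkb(geom, byte_order=1)


def decode_geometry(blob: bytes) -> BaseGeometry:
    if blob[:2] != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope_code = (flags >> 1) & 0b111
    envelope_len = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}[envelope_code]
    return shapely.from_wkb(blob[8 + envelope_len:])


def write_table(
    path: str | Path,
    table: str,
    geometries: list[BaseGeometry],
    properties: list[dict],
    crs: str | None,
    geometry_type: str = "GEOMETRY",
) -> None:
    srs = _srs_id(crs)
    keys: list[str] = []
    for props in properties:
        for k in props:
            if k not in keys:
                keys.append(k)
    con = sqlite3.connect(path)
    try:
        con.execute(f"PRAGMA application_id = {GPKG_APPLICATION_ID}")
        con.execute("PRAGMA user_version = 10200")
        con.executescript(_SRS_SETUP)
        con.execute(
            "INSERT OR IGNORE INTO gpkg_spatial_ref_sys VALUES (?,?,?,?,?,?)",
            (crs or "undefined", srs, "EPSG" if srs else "NONE", srs,
             crs or "undefined", None),
        )
        con.execute(f'DROP TABLE IF EXISTS "{table}"')
        cols = ", ".join(f'"{k}" TEXT' for k in keys)
        con.execute(
            f'CREATE TABLE "{table}" (fid INTEGER PRIMARY KEY AUTOINCREMENT, '
            f"geom BLOB{', ' + cols if cols else ''})"
        )
        bounds = shapely.total_bounds(geometries) if geometries else (None,) * 4
        con.execute("DELETE FROM gpkg_contents WHERE table_name = ?", (table,))
        con.execute(
            "INSERT INTO gpkg_contents VALUES (?,?,?,?,datetime('now'),?,?,?,?,?)",
            (table, "features", table, "", *[float(b) if b is not None else None for b in bounds], srs),
        )
        con.execute(
            "DELETE FROM gpkg_geometry_columns WHERE table_name = ?", (table,))
        con.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?,?,?,?,0,0)",
            (table, "geom", geometry_type, srs),
        )
        placeholders = ",".join("?" * (1 + len(keys)))
        rows = [
            (encode_geometry(g, srs), *[_to_text(props.get(k)) for k in keys])
            for g, props in zip(geometries, properties)
        ]
        colnames = ", ".join(['geom'] + [f'"{k}"' for k in keys])
        con.executemany(
            f'INSERT INTO "{table}" ({colnames}) VALUES ({placeholders})', rows)
        con.commit()
    finally:
        con.close()


def _to_text(value):
    if value is None or isinstance(value, (int, float, str)):
        return value
    return str(value)


def read_table(path: str | Path, table: str | None = None):
    """Return (geometries, properties, crs, table_name)."""
    con = sqlite3.connect(path)
    try:
        cur = con.execute(
            "SELECT table_name, column_name, srs_id FROM gpkg_geometry_columns")
        entries = cur.fetchall()
        if not entries:
            raise ValueError(f"{path}: no feature tables")
        if table is None:
            table, geom_col, srs = entries[0]
        else:
            match = [e for e in entries if e[0] == table]
            if not match:
                raise ValueError(f"{path}: no feature table {table!r}")
            table, geom_col, srs = match[0]
        crs = f"EPSG:{srs}" if srs else None
        cur = con.execute(f'SELECT * FROM "{table}"')
        colnames = [d[0] for d in cur.description]
        geoms, props = [], []
        for row in cur.fetchall():
            record = dict(zip(colnames, row))
            record.pop("fid", None)
            blob = record.pop(geom_col)
            geoms.append(decode_geometry(blob))
            props.append(record)
        return geoms, props, crs, table
    finally:
        con.close()
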