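"""GeoTIFF output for density grids via tifffile.

Writes a single-band float32 north-up raster with ModelPixelScale /
ModelTiepoint tags and a GDAL_NODATA tag so standard GIS tools can place it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .layers import DensityGrid

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113


def _geo_keys(crs: str | None) -> tuple:
    epsg = 32767  # user-defined
    if crs and crs.upper().startswith("EPSG:"):
        epsg = int(crs.split(":")[1])
    # KeyDirectoryVersion, KeyRevision, MinorRevision, NumberOfKeys, then keys:
    # GTModelTypeGeoKey=1 (projected), GTRasterTypeGeoKey=1 (PixelIsArea),
    # ProjectedCSTypeGeoKey=epsg
    return (1, 1, 0, 3,
            1024, 0, 1, 1,
            1025, 0, 1, 1,
            3072, 0, 1, epsg)


def write_density_geotiff(grid: DensityGrid, path: str | Path, crs: str | None = None) -> None:
    nrows = grid.values.shape[0]
    top = grid.origin[1] + nrows * grid.cell_size
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], top, 0.0)),
        (TAG_GEO_KEY_DIRECTORY, "H", 16, _geo_keys(crs)),
        (TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def read_density_geotiff(path: str | Path) -> DensityGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        scale = page.tags[TAG_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[TAG_MODEL_TIEPOINT].value
        nodata = float(page.tags[TAG_GDAL_NODATA].value)
    cell = float(scale[0])
    top = float(tiepoint[4])
    origin = (float(tiepoint[3]), top - values.shape[0] * cell)
    return DensityGrid(origin=origin, cell_size=cell, values=values, nodata=nodata)
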