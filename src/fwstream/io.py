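"""Raster I/O: GeoTIFF intermediates and multiband netCDF variable families.

GeoTIFF files carry the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, a minimal GeoKey directory declaring WGS84, and GDAL's
ASCII NoData tag), so intermediates open in any GIS.  Final variable
families are written as one netCDF file per family with the single layers
stacked along a ``band`` dimension, band codes and per-band storage schema
recorded as attributes; values are stored exactly as the catalog specifies
(scaled integers for temperature/slope/pH, floats for precipitation), so a
write/read round-trip is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

from .aggregation import scale_store_grid
from .catalog import LayerCatalogEntry
from .errors import GeometryError, InvalidParameterError
from .grid import EnvGrid, GridGeometry, Raster

__all__ = ["write_geotiff", "read_geotiff", "write_netcdf", "read_netcdf"]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey directory: version 1.1.0, 3 keys:
# GTModelType=2 (geographic), GTRasterType=1 (area), GeographicType=4326
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def write_geotiff(raster: Raster, path: str | Path) -> Path:
    """Write a single-band GeoTIFF preserving geotransform and NoData."""
    path = Path(path)
    geom = raster.geometry
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (geom.cellsize, geom.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.west, geom.north, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)))
    tifffile.imwrite(path, raster.values, extratags=extratags,
                     metadata={"units": raster.units})
    return path


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    north-up, square-cell GeoTIFF with the standard tags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise GeometryError(f"{path} lacks GeoTIFF georeferencing tags") from exc
        if abs(sx - sy) > 1e-12:
            raise GeometryError(f"{path}: non-square cells unsupported")
        west, north = tie[3], tie[4]
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            text = tags[_TAG_GDAL_NODATA].value
            nodata = float(text) if "." in text or "e" in text.lower() else int(text)
    geometry = GridGeometry(west=west, north=north, cellsize=float(sx),
                            nrows=values.shape[0], ncols=values.shape[1])
    return Raster(values=values, geometry=geometry, nodata=nodata)


def _coords(geom: GridGeometry) -> dict:
    lon = geom.west + (np.arange(geom.ncols) + 0.5) * geom.cellsize
    lat = geom.north - (np.arange(geom.nrows) + 0.5) * geom.cellsize
    return {"lat": lat, "lon": lon}


def write_netcdf(
    family: list[tuple[str, EnvGrid]],
    entries: list[LayerCatalogEntry],
    path: str | Path,
    apply_scaling: bool = True,
) -> Path:
    """Write one variable family (code, grid) pairs as a multiband netCDF.

    Every grid must share one geometry; every code must have a catalog
    entry, whose band order, scale factor, storage type and NoData are
    honoured.  With ``apply_scaling`` the grids are taken to be in physical
    units and converted to their stored representation here; otherwise they
    are written verbatim.
    """
    path = Path(path)
    by_code = {e.code: e for e in entries}
    chosen = []
    for code, grid in family:
        if code not in by_code:
            raise InvalidParameterError(f"code {code!r} is not in the catalog")
        chosen.append((by_code[code], grid))
    if not chosen:
        raise InvalidParameterError("empty variable family")
    geom = chosen[0][1].geometry
    for _, grid in chosen:
        if not geom.matches(grid.geometry):
            raise GeometryError("variable family mixes grid geometries")
    chosen.sort(key=lambda pair: pair[0].band)

    storages = {e.storage for e, _ in chosen}
    dtype = (np.int8 if storages == {"Byte"}
             else np.int32 if storages <= {"Byte", "Int32", "Int16"}
             else np.float64)
    stack = np.empty((len(chosen), geom.nrows, geom.ncols), dtype=dtype)
    for i, (entry, grid) in enumerate(chosen):
        stored = (scale_store_grid(grid, entry.scale_factor, entry.storage,
                                   entry.nodata)
                  if apply_scaling else grid)
        stack[i] = stored.values

    name = path.stem.replace("+", "_")
    ds = xr.Dataset(
        {name: (("band", "lat", "lon"), stack)},
        coords={"band": [e.band for e, _ in chosen], **_coords(geom)},
        attrs={
            "band_codes": ",".join(e.code for e, _ in chosen),
            "band_nodata": ",".join(repr(e.nodata) for e, _ in chosen),
            "band_scale_factors": ",".join(str(e.scale_factor) for e, _ in chosen),
            "band_storage": ",".join(e.storage for e, _ in chosen),
            "band_units": json.dumps([e.unit for e, _ in chosen]),
            "west": geom.west, "north": geom.north, "cellsize": geom.cellsize,
            "crs": "EPSG:4326",
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_netcdf(path: str | Path) -> dict[str, Raster]:
    """Read a family file back as {code: raster of stored values}."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        name = [v for v in ds.data_vars][0]
        var = ds[name]
        codes = ds.attrs["band_codes"].split(",")
        nodatas = [float(x) for x in ds.attrs["band_nodata"].split(",")]
        geom = GridGeometry(
            west=float(ds.attrs["west"]), north=float(ds.attrs["north"]),
            cellsize=float(ds.attrs["cellsize"]),
            nrows=var.shape[1], ncols=var.shape[2],
        )
        out = {}
        for i, code in enumerate(codes):
            out[code] = Raster(values=np.array(var[i]), geometry=geom,
                               nodata=nodatas[i])
    return out
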