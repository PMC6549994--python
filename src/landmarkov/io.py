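"""Raster and table I/O.

Two raster formats are supported:

* **ESRI ASCII grid** (``.asc``/``.txt``) — the human-readable fixture format;
* **GeoTIFF** (``.tif``/``.tiff``) — single band, read and written through
  :mod:`tifffile` with the ModelPixelScale/ModelTiepoint geo tags and the
  GDAL_NODATA tag.

Legends are CSV with header ``code,name``; matrices are CSV with legend names
as row/column labels.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, ContinuousRaster, GridTransform, Legend

__all__ = [
    "read_raster",
    "write_raster",
    "read_legend_csv",
    "write_legend_csv",
    "read_matrix_csv",
    "write_matrix_csv",
]

_ASCII_EXT = {".asc", ".txt", ".agr"}
_TIFF_EXT = {".tif", ".tiff"}

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42112


def read_raster(path, kind: str, legend: Legend | None = None,
                crs_tag: str = "", units: str = ""):
    """Read a single-band raster as categorical or continuous.

    Parameters
    ----------
    path
        GeoTIFF or ESRI ASCII grid file.
    kind
        ``"categorical"`` or ``"continuous"``.
    legend
        Optional legend for categorical rasters; derived from the data when
        omitted.
    """
    path = Path(path)
    if kind not in ("categorical", "continuous"):
        raise ValueError(f"kind must be 'categorical' or 'continuous', got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    ext = path.suffix.lower()
    if ext in _ASCII_EXT:
        values, transform, nodata = _read_ascii(path)
        file_crs = ""
    elif ext in _TIFF_EXT:
        values, transform, nodata, file_crs = _read_geotiff(path)
    else:
        raise ValueError(f"unsupported raster format {ext!r} for {path} "
                         "(expected GeoTIFF or ESRI ASCII grid)")
    crs = crs_tag or file_crs
    if kind == "categorical":
        nodata_int = int(round(nodata))
        rounded = np.rint(values)
        data = values != nodata
        if not np.allclose(values[data], rounded[data], atol=1e-6):
            raise ValueError(f"non-integer cell values in categorical raster {path}")
        ivals = rounded.astype(np.int64)
        ivals[~data] = nodata_int
        return CategoricalRaster(ivals, nodata_int, transform, crs, legend)
    mask = ~np.isfinite(values) | (values == nodata)
    return ContinuousRaster(values, mask, transform, crs, units, nodata_value=nodata)


def write_raster(raster, path) -> Path:
    """Write a raster in the format implied by the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _ASCII_EXT:
        _write_ascii(raster, path)
    elif ext in _TIFF_EXT:
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unsupported raster format {ext!r} for {path}")
    return path


# ---------------------------------------------------------------------------
# ESRI ASCII grid

def _read_ascii(path: Path):
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"missing georeference: ASCII grid {path} lacks '{req}' header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    values = np.array([v for row in rows for v in row], dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(f"ASCII grid {path}: expected {nrows * ncols} cells, got {values.size}")
    values = values.reshape(nrows, ncols)
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cellsize / 2
    else:
        raise ValueError(f"missing georeference: ASCII grid {path} lacks xllcorner")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise ValueError(f"missing georeference: ASCII grid {path} lacks yllcorner")
    y_top = yll + nrows * cellsize
    nodata = header.get("nodata_value", -9999.0)
    return values, GridTransform(x0, y_top, cellsize), nodata


def _format_cell(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _write_ascii(raster, path: Path) -> None:
    t = raster.transform
    nrows, ncols = raster.shape
    if isinstance(raster, CategoricalRaster):
        grid = raster.values.astype(float)
        nodata: float = float(raster.nodata)
    else:
        grid = raster.filled()
        nodata = float(raster.nodata_value)
    yll = t.y_origin - nrows * t.pixel_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {_format_cell(t.x_origin)}\n")
        fh.write(f"yllcorner {_format_cell(yll)}\n")
        fh.write(f"cellsize {_format_cell(t.pixel_size)}\n")
        fh.write(f"NODATA_value {_format_cell(nodata)}\n")
        for row in grid:
            fh.write(" ".join(_format_cell(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF via tifffile

def _read_geotiff(path: Path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim == 3:
            if values.shape[2] != 1:
                raise ValueError(f"GeoTIFF {path} is multi-band; expected single band")
            values = values[:, :, 0]
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"missing georeference: GeoTIFF {path} lacks geo tags")
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        tie = tags[_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z)
        i, j = tie[0], tie[1]
        x, y = tie[3], tie[4]
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ValueError(f"GeoTIFF {path}: non-square pixels {sx} x {sy} unsupported")
        x0 = x - i * sx
        y0 = y + j * sy
        nodata = -9999.0
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA].value).strip("\x00 "))
        desc = tags.get(270)
        crs = str(desc.value) if desc is not None else ""
    return values, GridTransform(x0, y0, sx), nodata, crs


def _write_geotiff(raster, path: Path) -> None:
    import tifffile

    t = raster.transform
    if isinstance(raster, CategoricalRaster):
        data = raster.values.astype(np.int32)
        nodata: float = float(raster.nodata)
    else:
        data = raster.filled().astype(np.float64)
        nodata = float(raster.nodata_value)
    nodata_s = (str(int(nodata)) if float(nodata).is_integer() else repr(nodata)) + "\x00"
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_size, t.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_GDAL_NODATA, "s", len(nodata_s), nodata_s),
    ]
    tifffile.imwrite(path, data, extratags=extratags, description=raster.crs_tag)


# ---------------------------------------------------------------------------
# Legend and matrix CSV

def read_legend_csv(path) -> Legend:
    path = Path(path)
    entries: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["code", "name"]:
            raise ValueError(f"legend CSV {path} must have header 'code,name'")
        for row in reader:
            if not row or not row[0].strip():
                continue
            entries.append((int(row[0]), row[1].strip()))
    return Legend(entries)


def write_legend_csv(legend: Legend, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name"])
        writer.writerows(legend.entries)
    return path


def write_matrix_csv(matrix: np.ndarray, legend: Legend, path, float_format=None) -> Path:
    """Write a K x K matrix as CSV labelled with legend names."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(matrix), index=legend.names, columns=legend.names)
    df.to_csv(path, float_format=float_format)
    return path


def read_matrix_csv(path, legend: Legend | None = None) -> tuple[np.ndarray, Legend]:
    """Read a legend-labelled K x K matrix CSV; returns (matrix, legend).

    When ``legend`` is given, rows/columns are reordered to match it.
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix CSV {path}: row labels != column labels")
    if legend is not None:
        df = df.loc[legend.names, legend.names]
        return df.to_numpy(dtype=float), legend
    made = Legend(list(enumerate(df.index)))
    return df.to_numpy(dtype=float), made
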