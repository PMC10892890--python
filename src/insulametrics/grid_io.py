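"""Readers/writers for elevation grids and land/sea rasters.

Two plain-text formats are supported:

* **ESRI ASCII grid** (``.asc``): ncols/nrows/xllcorner/yllcorner/cellsize
  and optional NODATA_value header lines, then a row-major body, north row
  first.
* **Delimited matrix**: a bare rectangular numeric matrix, whitespace- or
  comma-separated, ``#`` comments allowed.

Land/sea rasters use the same containers with an integer code per cell:
0 = sea, 1 = land, 2 = land belonging to the focal island (sets the focal
mask; the centre is the cell nearest the focal centroid).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import DegenerateInputError, GridFormatError, ValidationError
from .geo_metrics import ElevationGrid, LandSeaRaster

GridFormat = Literal["esri_ascii", "matrix"]

_ESRI_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _parse_matrix(text: str) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as e:
            raise GridFormatError(f"line {lineno}: non-numeric token ({e})") from None
    if not rows:
        raise GridFormatError("no numeric rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise GridFormatError(f"ragged rows: row widths {sorted(widths)}")
    return np.array(rows, dtype=float)


def _parse_esri_ascii(text: str) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ESRI_HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise GridFormatError(f"bad header value in {line!r}") from None
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"ESRI ASCII header missing {key}")
    values = _parse_matrix("\n".join(lines[body_start:]))
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"body shape {values.shape} does not match header (nrows={nrows}, ncols={ncols})"
        )
    return values, header


def _sniff_format(text: str) -> GridFormat:
    for line in text.splitlines():
        if line.strip():
            first = line.split()[0].lower()
            return "esri_ascii" if first in _ESRI_HEADER_KEYS else "matrix"
    raise GridFormatError("empty file")


def read_elevation_grid(
    path: str | Path,
    format: GridFormat | None = None,
    cell_size: float | None = None,
) -> ElevationGrid:
    """Read an elevation grid; format auto-detected unless given.

    ``cell_size`` (metres) overrides the file's cellsize for matrix files,
    which carry no spacing of their own (default 1.0).
    """
    text = Path(path).read_text()
    fmt = format or _sniff_format(text)
    if fmt == "esri_ascii":
        values, header = _parse_esri_ascii(text)
        nodata = header.get("nodata_value")
        mask = np.zeros(values.shape, dtype=bool) if nodata is None else values == nodata
        size = cell_size if cell_size is not None else header["cellsize"]
    elif fmt == "matrix":
        values = _parse_matrix(text)
        mask = ~np.isfinite(values)
        size = cell_size if cell_size is not None else 1.0
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if mask.all():
        raise DegenerateInputError("grid has no valid (non-nodata) cells")
    values = values.copy()
    values[mask] = 0.0  # placeholder under the mask; never used
    return ElevationGrid(values=values, cell_size=size, nodata_mask=mask)


def write_elevation_grid(
    grid: ElevationGrid,
    path: str | Path,
    format: GridFormat = "esri_ascii",
    nodata_value: float = -9999.0,
) -> None:
    buf = io.StringIO()
    body = grid.values.copy()
    if grid.nodata_mask.any():
        if format == "matrix":
            body[grid.nodata_mask] = np.nan
        else:
            body[grid.nodata_mask] = nodata_value
    if format == "esri_ascii":
        nrows, ncols = grid.shape
        buf.write(f"ncols {ncols}\n")
        buf.write(f"nrows {nrows}\n")
        buf.write("xllcorner 0.0\n")
        buf.write("yllcorner 0.0\n")
        buf.write(f"cellsize {float(grid.cell_size)!r}\n")
        buf.write(f"NODATA_value {float(nodata_value)!r}\n")
    elif format != "matrix":
        raise ValueError(f"unknown format {format!r}")
    for row in body:
        buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_land_sea(
    path: str | Path,
    cell_size_km: float | None = None,
    format: GridFormat | None = None,
) -> LandSeaRaster:
    """Read a coded land/sea raster (0 sea, 1 land, 2 focal-island land)."""
    text = Path(path).read_text()
    fmt = format or _sniff_format(text)
    if fmt == "esri_ascii":
        codes, header = _parse_esri_ascii(text)
        size = cell_size_km if cell_size_km is not None else header["cellsize"]
    else:
        codes = _parse_matrix(text)
        size = cell_size_km if cell_size_km is not None else 1.0
    if not np.isin(codes, (0, 1, 2)).all():
        raise ValidationError("land/sea raster codes must be 0 (sea), 1 (land) or 2 (focal)")
    return LandSeaRaster(
        values=(codes >= 1).astype(np.uint8),
        cell_size_km=size,
        focal_mask=codes == 2,
    )


def write_land_sea(raster: LandSeaRaster, path: str | Path, format: GridFormat = "esri_ascii") -> None:
    codes = raster.values.astype(float)
    codes[raster.focal_mask] = 2.0
    write_elevation_grid(
        ElevationGrid(values=codes, cell_size=raster.cell_size_km),
        path,
        format=format,
    )
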