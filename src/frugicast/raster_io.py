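"""Raster reading and writing.

Two single-layer formats are supported, chosen by file suffix:

* ``.asc`` — ESRI ASCII grid, the plain-text interchange format
  (``ncols``/``nrows``/``xllcorner``/``yllcorner``/``cellsize``/
  ``NODATA_value`` header, then rows north-to-south).
* ``.tif`` / ``.tiff`` — TIFF via :mod:`tifffile`, with the grid geometry
  carried as JSON in the ImageDescription tag.

Grids follow the package convention of row 0 at the south (lower-left
origin); ASCII rows are flipped on the way in and out.  NaN cells are
written as the nodata value and come back as NaN.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grids import GridSpec

__all__ = ["read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


def write_raster(
    grid: np.ndarray, spec: GridSpec, path: str | Path, nodata: float = DEFAULT_NODATA
) -> Path:
    """Write one layer; format chosen from the path suffix (.asc or .tif)."""
    path = Path(path)
    arr = np.asarray(grid, dtype=float)
    if arr.shape != spec.shape:
        raise ValueError(
            f"{path.name}: array shape {arr.shape} does not match grid {spec.shape}"
        )
    if path.suffix.lower() == ".asc":
        _write_ascii(arr, spec, path, nodata)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(arr, spec, path, nodata)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r} (use .asc or .tif)")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read one layer and its GridSpec; nodata cells become NaN."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    if path.suffix.lower() == ".asc":
        return _read_ascii(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unsupported raster format {path.suffix!r} (use .asc or .tif)")


def _write_ascii(arr: np.ndarray, spec: GridSpec, path: Path, nodata: float) -> None:
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin[0]:.10g}\n"
        f"yllcorner {spec.origin[1]:.10g}\n"
        f"cellsize {spec.cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    # ASCII grids run north to south; our row 0 is the southernmost
    body = "\n".join(
        " ".join(f"{v:.10g}" for v in row) for row in out[::-1]
    )
    path.write_text(header + body + "\n")


def _read_ascii(path: Path) -> tuple[np.ndarray, GridSpec]:
    tokens: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            tokens[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in tokens:
            raise ValueError(f"{path.name}: missing ASCII grid header field {required!r}")
    n_rows, n_cols = int(tokens["nrows"]), int(tokens["ncols"])
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path.name}: body shape {data.shape} disagrees with header "
            f"({n_rows}, {n_cols})"
        )
    nodata = tokens.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=tokens["cellsize"],
        origin=(tokens["xllcorner"], tokens["yllcorner"]),
        cell_area=tokens["cellsize"] ** 2,
    )
    return data[::-1].copy(), spec


def _write_tiff(arr: np.ndarray, spec: GridSpec, path: Path, nodata: float) -> None:
    out = np.where(np.isfinite(arr), arr, nodata).astype(np.float64)
    meta = {
        "cell_size": spec.cell_size,
        "origin": list(spec.origin),
        "cell_area": spec.cell_area,
        "nodata": nodata,
    }
    tifffile.imwrite(path, out, description=json.dumps(meta))


def _read_tiff(path: Path) -> tuple[np.ndarray, GridSpec]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(float)
        desc = tif.pages[0].description
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-layer 2-D TIFF")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    nodata = meta.get("nodata", DEFAULT_NODATA)
    arr[arr == nodata] = np.nan
    spec = GridSpec(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        cell_area=float(meta.get("cell_area", 1.0)),
    )
    return arr, spec
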