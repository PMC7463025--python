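"""Standard-format readers and writers.

Vector data travel as GeoJSON FeatureCollections (shapely geometries,
properties preserved opaquely), rasters as ESRI ASCII grids (plain text,
lower-left origin), tables as CSV, configuration as JSON. All round-trips
are identity on the data model; a ``crs`` member on a FeatureCollection
is carried through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grid import GridSpec

NODATA = -9999.0

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_json",
    "read_json",
    "write_table",
    "read_table",
    "write_grid_cells",
    "read_grid_cells",
]


# -- GeoJSON ----------------------------------------------------------------


def write_geojson(path, features, crs=None):
    """Write [(geometry, properties), ...] as a FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props or {}}
            for geom, props in features
        ],
    }
    if crs is not None:
        collection["crs"] = crs
    Path(path).write_text(json.dumps(collection))


def read_geojson(path):
    """Read a FeatureCollection; returns ([(geometry, properties)], crs)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed GeoJSON at line {exc.lineno}") from exc
    features = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            features.append((shape(feat["geometry"]), feat.get("properties", {})))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"{path}: malformed feature index {i}") from exc
    return features, doc.get("crs")


# -- ESRI ASCII grid --------------------------------------------------------


def write_ascii_grid(path, values, origin, cell_size_m, nodata=NODATA):
    """Write a grid-shaped array (row 0 = south) as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {n_cols}\nnrows {n_rows}\n"
        f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size_m}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")  # ASCII grids store north first


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (values, origin, cell_size)."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        meta[key.lower()] = float(val)
    values = np.loadtxt(lines[6:])
    values = np.atleast_2d(values)[::-1]
    nodata = meta.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, (meta["xllcorner"], meta["yllcorner"]), meta["cellsize"]


# -- JSON / CSV -------------------------------------------------------------


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_table(path, df: pd.DataFrame):
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- lattice round-trip -----------------------------------------------------


def write_grid_cells(path, grid: GridSpec, layers=None):
    """Persist the lattice (and optional grid-shaped layers) as one CSV."""
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    df = pd.DataFrame(
        {
            "cell_id": grid.cell_id(rows, cols).ravel(),
            "row": rows.ravel(),
            "col": cols.ravel(),
            "marine": grid.marine_mask.ravel().astype(int),
            "zone": grid.zone_label.ravel(),
            "zone_name": grid.zone_name.ravel(),
        }
    )
    for name, values in (layers or {}).items():
        df[name] = np.asarray(values).ravel()
    df.attrs["origin"] = grid.origin
    with open(path, "w") as fh:
        fh.write(f"# origin={grid.origin[0]},{grid.origin[1]} cell_size={grid.cell_size_m}\n")
        df.to_csv(fh, index=False)


def read_grid_cells(path):
    """Inverse of :func:`write_grid_cells`; returns (grid, layers dict)."""
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    try:
        parts = dict(item.split("=") for item in header.strip("#\n ").split())
        ox, oy = (float(v) for v in parts["origin"].split(","))
        cell_size = float(parts["cell_size"])
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: malformed grid header line") from exc
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    shape2 = (n_rows, n_cols)
    order = np.lexsort((df["col"], df["row"]))
    df = df.iloc[order]
    grid = GridSpec(
        origin=(ox, oy),
        cell_size_m=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
        marine_mask=df["marine"].to_numpy().reshape(shape2).astype(bool),
        zone_label=df["zone"].fillna("").to_numpy().reshape(shape2),
        zone_name=df["zone_name"].fillna("").to_numpy().reshape(shape2),
    )
    extra = {
        c: df[c].to_numpy().reshape(shape2)
        for c in df.columns
        if c not in ("cell_id", "row", "col", "marine", "zone", "zone_name")
    }
    return grid, extra
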