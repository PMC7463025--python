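"""Ecogeographic predictor layers on the analysis lattice.

Continuous layers: water depth (m), seabed slope (degrees) and complexity
(m, both from 3x3 neighbourhoods), straight-line distance to coast (m),
around-land cost distances (m) to reef crest, boat ramps, sanctuary zones
and reef passages, and ordinary-kriged surfaces (e.g. SST) from point
measurements. One categorical layer samples the benthic habitat map by
majority area per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from shapely import STRtree, box
from shapely.geometry import Point

from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorLayer",
    "SphericalVariogram",
    "MissingValueError",
    "euclidean_distance_layer",
    "cost_distance_layer",
    "slope_complexity_layers",
    "krige_layer",
    "ordinary_kriging_weights",
    "sample_categorical",
    "assemble_feature_table",
    "grid_feature_frame",
]

UNCLASSIFIED = "unclassified"


class MissingValueError(ValueError):
    """A responding cell lacks a value in some predictor layer."""


@dataclass
class PredictorLayer:
    """One per-cell variable, defined on marine cells.

    ``values`` is grid-shaped; NaN (continuous) or ``""`` (categorical)
    off-marine, ``inf`` marks cells unreachable by a cost distance.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be 'continuous' or 'categorical'")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def euclidean_distance_layer(grid: GridSpec, target, name: str = "dist") -> PredictorLayer:
    """Shortest straight-line distance (m) from each marine cell centroid
    to ``target``; cells whose footprint intersects the target get 0."""
    if target is None or target.is_empty:
        raise ValueError("target geometry is empty")
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    rows, cols = np.nonzero(grid.marine_mask)
    cx, cy = grid.cell_center(rows, cols)
    for r, c, x, y in zip(rows, cols, cx, cy):
        values[r, c] = Point(x, y).distance(target)
    # zero on intersecting cells
    for r, c in zip(rows, cols):
        if values[r, c] > 0 and values[r, c] < grid.cell_size_m:
            xmin, ymin, xmax, ymax = grid.cell_bounds(r, c)
            if box(xmin, ymin, xmax, ymax).intersects(target):
                values[r, c] = 0.0
    return PredictorLayer(name=name, kind="continuous", values=values, units="m")


def _marine_adjacency(grid: GridSpec):
    """Sparse 8-connected adjacency of marine cells; returns (graph, index
    map from (row, col) to node, node -> (row, col) arrays)."""
    rows, cols = np.nonzero(grid.marine_mask)
    n = len(rows)
    node = -np.ones((grid.n_rows, grid.n_cols), dtype=int)
    node[rows, cols] = np.arange(n)
    cs = grid.cell_size_m
    src, dst, wgt = [], [], []
    steps = [(0, 1, cs), (1, 0, cs), (1, 1, cs * np.sqrt(2)), (1, -1, cs * np.sqrt(2))]
    for dr, dc, w in steps:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < grid.n_rows) & (c2 >= 0) & (c2 < grid.n_cols)
        ok[ok] &= grid.marine_mask[r2[ok], c2[ok]]
        src.extend(node[rows[ok], cols[ok]])
        dst.extend(node[r2[ok], c2[ok]])
        wgt.extend([w] * int(ok.sum()))
    graph = coo_matrix((wgt, (src, dst)), shape=(n, n)).tocsr()
    return graph, node, rows, cols


def cost_distance_layer(grid: GridSpec, target, name: str = "cost") -> PredictorLayer:
    """Around-land shortest-path distance (m) over the marine lattice.

    8-connected moves (orthogonal = cell size, diagonal = cell size * √2)
    from every marine cell whose footprint touches ``target`` (those start
    at 0). Unreachable cells are flagged ``inf`` and later excluded from
    the feature table with a warning.
    """
    if target is None or target.is_empty:
        raise ValueError("target geometry is empty")
    graph, node, rows, cols = _marine_adjacency(grid)
    tree = STRtree(
        [box(*grid.cell_bounds(r, c)) for r, c in zip(rows, cols)]
    )
    hits = tree.query(target, predicate="intersects")
    sources = np.unique(np.atleast_1d(hits))
    if len(sources) == 0:
        # a shore-bound target (e.g. a boat ramp on the waterline) may sit
        # inside a land cell; snap it to the nearest marine cell
        nearest = tree.nearest(target)
        if nearest is None:
            raise ValueError("target geometry touches no marine cell")
        sources = np.atleast_1d(nearest)
        logger.info("target '%s' snapped to nearest marine cell", name)
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    values[rows, cols] = dist
    n_unreachable = int(np.isinf(dist).sum())
    if n_unreachable:
        logger.warning("%d marine cells unreachable from '%s'", n_unreachable, name)
    return PredictorLayer(name=name, kind="continuous", values=values, units="m")


# ---------------------------------------------------------------------------
# terrain derivatives
# ---------------------------------------------------------------------------


def slope_complexity_layers(depth, grid: GridSpec):
    """Seabed slope (degrees) and complexity (m) from 3x3 neighbourhoods.

    Slope is the maximum gradient magnitude to any marine neighbour,
    ``atan(|dz| / distance)`` in degrees; complexity is the population
    standard deviation of depth over the marine neighbourhood (self
    included). Edge cells use whatever neighbours exist; isolated cells
    get 0 for both (logged).
    """
    z = np.asarray(getattr(depth, "values", depth), dtype=float)
    cs = grid.cell_size_m
    slope = np.full_like(z, np.nan)
    complexity = np.full_like(z, np.nan)
    rows, cols = np.nonzero(grid.marine_mask)
    isolated = 0
    for r, c in zip(rows, cols):
        zc = z[r, c]
        grads, vals = [], [zc]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < grid.n_rows and 0 <= c2 < grid.n_cols and grid.marine_mask[r2, c2]:
                    dist = cs * np.hypot(dr, dc)
                    grads.append(abs(z[r2, c2] - zc) / dist)
                    vals.append(z[r2, c2])
        if not grads:
            isolated += 1
            slope[r, c] = 0.0
            complexity[r, c] = 0.0
        else:
            slope[r, c] = np.degrees(np.arctan(max(grads)))
            complexity[r, c] = float(np.std(vals))
    if isolated:
        logger.info("%d isolated marine cells assigned slope=complexity=0", isolated)
    return (
        PredictorLayer("slope", "continuous", slope, units="degrees"),
        PredictorLayer("complexity", "continuous", complexity, units="m"),
    )


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalVariogram:
    """Spherical semivariogram gamma(h) with nugget, sill and range."""

    nugget: float = 0.0
    sill: float = 1.0
    range_m: float = 5_000.0

    def __post_init__(self):
        if self.range_m <= 0:
            raise ValueError("range must be positive")
        if not (self.sill >= self.nugget >= 0):
            raise ValueError("require sill >= nugget >= 0")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        hr = np.clip(h / self.range_m, 0.0, 1.0)
        gamma = self.nugget + (self.sill - self.nugget) * (1.5 * hr - 0.5 * hr**3)
        return np.where(h == 0.0, 0.0, gamma)


def ordinary_kriging_weights(sample_xy, target_xy, variogram):
    """Solve the ordinary-kriging system for one target location.

    Returns the weight vector (sums to 1 by the Lagrange constraint).
    """
    sample_xy = np.asarray(sample_xy, dtype=float)
    k = len(sample_xy)
    d = np.linalg.norm(sample_xy[:, None, :] - sample_xy[None, :, :], axis=-1)
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = variogram(d)
    A[k, :k] = 1.0
    A[:k, k] = 1.0
    A[k, k] = 0.0
    b = np.empty(k + 1)
    b[:k] = variogram(np.linalg.norm(sample_xy - np.asarray(target_xy, dtype=float), axis=-1))
    b[k] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:k]


def krige_layer(
    samples,
    grid: GridSpec,
    variogram: SphericalVariogram | None = None,
    max_neighbors: int = 12,
    name: str = "kriged",
) -> PredictorLayer:
    """Ordinary-kriging interpolation of point samples onto marine cells.

    Uses the nearest ``max_neighbors`` samples per cell (the 12-point
    moving neighbourhood of standard GIS kriging tools). Samples at
    duplicated locations are averaged first (logged).
    """
    if variogram is None:
        variogram = SphericalVariogram()
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or len(arr) < 2:
        raise ValueError("samples must be an (n>=2, 3) array of x, y, value")
    df = pd.DataFrame(arr, columns=["x", "y", "v"])
    dedup = df.groupby(["x", "y"], as_index=False)["v"].mean()
    if len(dedup) < len(df):
        logger.info("averaged %d duplicate sample locations", len(df) - len(dedup))
    if len(dedup) < 2:
        raise ValueError("fewer than 2 distinct sample locations")
    xy = dedup[["x", "y"]].to_numpy()
    vals = dedup["v"].to_numpy()
    tree = cKDTree(xy)
    k = min(max_neighbors, len(xy))
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    rows, cols = np.nonzero(grid.marine_mask)
    cx, cy = grid.cell_center(rows, cols)
    _, idx = tree.query(np.column_stack([cx, cy]), k=k)
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    for r, c, x, y, nbr in zip(rows, cols, cx, cy, idx):
        nbr = np.atleast_1d(nbr)
        w = ordinary_kriging_weights(xy[nbr], (x, y), variogram)
        values[r, c] = float(w @ vals[nbr])
    return PredictorLayer(name=name, kind="continuous", values=values, units="")


# ---------------------------------------------------------------------------
# categorical habitat
# ---------------------------------------------------------------------------


def sample_categorical(
    habitat_polygons, grid: GridSpec, name: str = "habitat"
) -> PredictorLayer:
    """Majority-area habitat class per marine cell.

    Ties are broken by lexicographic class order; cells covered by no
    polygon get ``"unclassified"`` (later excluded from the feature table
    with a warning).
    """
    labels = [lbl for lbl, _ in habitat_polygons]
    geoms = [geom for _, geom in habitat_polygons]
    tree = STRtree(geoms)
    values = np.full((grid.n_rows, grid.n_cols), "", dtype=object)
    rows, cols = np.nonzero(grid.marine_mask)
    n_unclassified = 0
    for r, c in zip(rows, cols):
        cell = box(*grid.cell_bounds(r, c))
        areas: dict[str, float] = {}
        for gi in tree.query(cell, predicate="intersects"):
            a = cell.intersection(geoms[gi]).area
            if a > 0:
                areas[labels[gi]] = areas.get(labels[gi], 0.0) + a
        if not areas:
            values[r, c] = UNCLASSIFIED
            n_unclassified += 1
        else:
            # deterministic: max area, ties -> lexicographically smallest
            top = max(areas.values())
            cands = sorted(k for k, v in areas.items() if v == top)
            values[r, c] = cands[0]
    if n_unclassified:
        logger.warning("%d marine cells have no habitat coverage", n_unclassified)
    return PredictorLayer(name=name, kind="categorical", values=values)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def _check_alignment(grid: GridSpec, layers):
    for layer in layers:
        if layer.values.shape != (grid.n_rows, grid.n_cols):
            raise ValueError(f"layer '{layer.name}' not aligned with the grid")


def _cells_frame(grid: GridSpec, layers, cell_ids):
    rows, cols = grid.rowcol(cell_ids)
    data = {}
    for layer in layers:
        data[layer.name] = layer.values[rows, cols]
    return pd.DataFrame(data, index=cell_ids)


def assemble_feature_table(
    grid: GridSpec,
    layers,
    response,
    effort,
) -> pd.DataFrame:
    """Design matrix: one row per responding (presence/absence) cell.

    Columns: the predictor layers in the order given, then ``response``,
    ``effort_m`` and ``cell_id``. Missing continuous values raise
    :class:`MissingValueError` naming the offending cells and layers;
    unreachable (inf) or unclassified cells are dropped with a warning.
    """
    _check_alignment(grid, layers)
    cell_ids = response.responding_cells
    df = _cells_frame(grid, layers, cell_ids)

    problems = []
    drop = np.zeros(len(df), dtype=bool)
    for layer in layers:
        colvals = df[layer.name]
        if layer.kind == "continuous":
            vals = colvals.to_numpy(dtype=float)
            nan_mask = np.isnan(vals)
            if nan_mask.any():
                problems.append((layer.name, list(df.index[nan_mask])))
            inf_mask = np.isinf(vals)
            if inf_mask.any():
                logger.warning(
                    "dropping %d cells unreachable in layer '%s'",
                    int(inf_mask.sum()), layer.name,
                )
                drop |= inf_mask
        else:
            bad = colvals.to_numpy() == UNCLASSIFIED
            if bad.any():
                logger.warning(
                    "dropping %d unclassified cells in layer '%s'",
                    int(bad.sum()), layer.name,
                )
                drop |= bad
    if problems:
        detail = "; ".join(f"{name}: cells {cells[:5]}" for name, cells in problems)
        raise MissingValueError(f"missing predictor values ({detail})")

    df = df.loc[~drop]
    kept = df.index.to_numpy()
    rows, cols = grid.rowcol(kept)
    df = df.assign(
        response=response.response[rows, cols].astype(int),
        effort_m=effort.effort_m[rows, cols],
        cell_id=kept,
    )
    return df.reset_index(drop=True)


def grid_feature_frame(grid: GridSpec, layers) -> pd.DataFrame:
    """Predictor values for every marine cell (for surface prediction).

    Cells with missing/unreachable/unclassified values are dropped with a
    warning; the returned frame carries a ``cell_id`` column.
    """
    _check_alignment(grid, layers)
    cell_ids = grid.marine_cell_ids()
    df = _cells_frame(grid, layers, cell_ids)
    drop = np.zeros(len(df), dtype=bool)
    for layer in layers:
        if layer.kind == "continuous":
            vals = df[layer.name].to_numpy(dtype=float)
            drop |= ~np.isfinite(vals)
        else:
            drop |= df[layer.name].to_numpy() == UNCLASSIFIED
    if drop.any():
        logger.warning("dropping %d marine cells with incomplete predictors", int(drop.sum()))
    df = df.loc[~drop]
    df = df.assign(cell_id=df.index.to_numpy())
    return df.reset_index(drop=True)
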