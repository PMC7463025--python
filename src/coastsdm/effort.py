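"""Survey effort gridding and the presence / true-absence response.

Tracklines are buffered by 250 m to delimit the surveyed corridor, the
trackline length falling in each 500 m cell becomes the effort layer, a
cell with at least one sighting becomes a presence cell, and absences are
drawn from the surveyed, sighting-free cells in decreasing order of
effort ("effort-ranked true absences"), matched in number to the
presences. The effort of the last absence selected is reported as the
absence threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "EffortMap",
    "ResponseGrid",
    "InsufficientAbsencesError",
    "buffer_tracklines",
    "effort_per_cell",
    "assign_presence",
    "select_absences",
]


class InsufficientAbsencesError(ValueError):
    """Raised when fewer candidate absence cells exist than presences."""


@dataclass
class EffortMap:
    """Per-cell survey-track length in metres."""

    grid: GridSpec
    effort_m: np.ndarray  # (n_rows, n_cols), 0 where unsurveyed

    @property
    def total_m(self) -> float:
        return float(self.effort_m.sum())


@dataclass
class ResponseGrid:
    """Balanced presence / true-absence response on the lattice.

    ``response`` holds 1 (presence), 0 (absence) or -1 (undefined).
    """

    grid: GridSpec
    response: np.ndarray  # (n_rows, n_cols) int8
    absence_threshold_m: float | None

    @property
    def presence_cells(self) -> np.ndarray:
        rows, cols = np.nonzero(self.response == 1)
        return np.sort(self.grid.cell_id(rows, cols))

    @property
    def absence_cells(self) -> np.ndarray:
        rows, cols = np.nonzero(self.response == 0)
        return np.sort(self.grid.cell_id(rows, cols))

    @property
    def responding_cells(self) -> np.ndarray:
        rows, cols = np.nonzero(self.response >= 0)
        return np.sort(self.grid.cell_id(rows, cols))


# ---------------------------------------------------------------------------


def buffer_tracklines(tracklines, buffer_m: float = 250.0):
    """Union of flat-capped buffers around each survey line.

    Flat (butt) caps keep a single straight segment's corridor an exact
    rectangle of area ``length * 2 * buffer_m``.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    lines = getattr(tracklines, "lines", tracklines)
    if not lines:
        return Polygon()
    geoms = [
        LineString(np.asarray(line, dtype=float)).buffer(buffer_m, cap_style="flat")
        for line in lines
    ]
    return unary_union(geoms)


def _segment_cell_lengths(p, q, grid: GridSpec, effort: np.ndarray) -> float:
    """Distribute one segment's length over the cells it crosses.

    Walks the segment parametrically, splitting it at every grid line it
    crosses; each piece is attributed to the cell containing its midpoint.
    Pieces outside the lattice are dropped. Returns the dropped length.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    seg_len = float(np.hypot(*d))
    if seg_len == 0:
        return 0.0
    x0, y0 = grid.origin
    cs = grid.cell_size_m
    ts = [0.0, 1.0]
    for axis, o in ((0, x0), (1, y0)):
        if d[axis] != 0:
            lo = min(p[axis], q[axis])
            hi = max(p[axis], q[axis])
            j_lo = int(np.ceil((lo - o) / cs))
            j_hi = int(np.floor((hi - o) / cs))
            for j in range(j_lo, j_hi + 1):
                t = (o + j * cs - p[axis]) / d[axis]
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = np.unique(np.asarray(ts))
    mids = p + np.outer((ts[:-1] + ts[1:]) / 2.0, d)
    lengths = np.diff(ts) * seg_len
    rows, cols = grid.point_to_rowcol(mids[:, 0], mids[:, 1])
    inside = grid.in_bounds(rows, cols)
    np.add.at(effort, (rows[inside], cols[inside]), lengths[inside])
    return float(lengths[~inside].sum())


def effort_per_cell(tracklines, grid: GridSpec) -> EffortMap:
    """Length of survey track per grid cell (metres).

    Exact parametric clipping: the per-cell lengths of each segment sum to
    the segment length inside the lattice. Track outside the lattice is
    clipped silently and logged.
    """
    effort = np.zeros((grid.n_rows, grid.n_cols))
    dropped = 0.0
    lines = getattr(tracklines, "lines", tracklines)
    for line in lines:
        arr = np.asarray(line, dtype=float)
        for i in range(len(arr) - 1):
            dropped += _segment_cell_lengths(arr[i], arr[i + 1], grid, effort)
    if dropped > 0:
        logger.warning("clipped %.1f m of track outside the grid", dropped)
    return EffortMap(grid=grid, effort_m=effort)


def assign_presence(sightings, grid: GridSpec) -> np.ndarray:
    """Cells containing at least one sighting (sorted unique cell ids).

    Boundary sightings follow the half-open cell convention; duplicate
    sightings in one cell collapse. A sighting over a non-marine cell is
    still counted but logged as suspicious.
    """
    pts = np.asarray(getattr(sightings, "points", sightings), dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.empty(0, dtype=int)
    rows, cols = grid.point_to_rowcol(pts[:, 0], pts[:, 1])
    inside = grid.in_bounds(rows, cols)
    if not inside.all():
        logger.warning("%d sightings outside the lattice dropped", int((~inside).sum()))
    rows, cols = rows[inside], cols[inside]
    on_land = ~grid.marine_mask[rows, cols]
    if on_land.any():
        logger.warning("%d sightings fall on non-marine cells", int(on_land.sum()))
    return np.unique(grid.cell_id(rows, cols))


def select_absences(effort: EffortMap, presence_cells, grid: GridSpec) -> ResponseGrid:
    """Effort-ranked true-absence selection, balanced with presences.

    Candidates are surveyed marine cells without a sighting; the
    ``len(presence_cells)`` with the highest effort become absences. Ties
    at the selection boundary are broken by ascending cell index (logged).
    """
    presence_cells = np.asarray(presence_cells, dtype=int)
    response = np.full((grid.n_rows, grid.n_cols), -1, dtype=np.int8)
    prow, pcol = grid.rowcol(presence_cells)
    response[prow, pcol] = 1

    n_pres = len(presence_cells)
    if n_pres == 0:
        return ResponseGrid(grid=grid, response=response, absence_threshold_m=None)

    surveyed = (effort.effort_m > 0) & grid.marine_mask & (response != 1)
    rows, cols = np.nonzero(surveyed)
    cand_ids = grid.cell_id(rows, cols)
    cand_eff = effort.effort_m[rows, cols]
    if len(cand_ids) < n_pres:
        raise InsufficientAbsencesError(
            f"need {n_pres} absence candidates, only {len(cand_ids)} surveyed "
            f"sighting-free cells available (deficit {n_pres - len(cand_ids)})"
        )
    order = np.lexsort((cand_ids, -cand_eff))  # effort desc, cell id asc
    chosen = order[:n_pres]
    threshold = float(cand_eff[chosen[-1]])
    n_tied = int(np.sum(cand_eff == threshold))
    if n_tied > 1:
        logger.info(
            "effort ties at the absence threshold (%.1f m, %d cells); "
            "broken by cell index", threshold, n_tied,
        )
    arow, acol = grid.rowcol(cand_ids[chosen])
    response[arow, acol] = 0
    return ResponseGrid(grid=grid, response=response, absence_threshold_m=threshold)
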