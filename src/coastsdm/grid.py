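"""Analysis lattice shared by every pipeline stage.

The study area is discretised on a regular 500 x 500 m grid (row-major,
origin at the lower-left corner, half-open cells ``[x, x+cs) x [y, y+cs)``).
Each cell carries a marine/land flag and a management-zone label
(sanctuary ``SZ``, recreation ``RZ``, general-use ``GUZ``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONE_CODES = ("SZ", "RZ", "GUZ")


class InvalidConfigError(ValueError):
    """Raised when a configuration cannot describe a usable study area."""


@dataclass
class GridSpec:
    """Regular analysis lattice.

    Parameters
    ----------
    origin : (x0, y0)
        Lower-left corner of cell (row 0, col 0), projected metres.
    cell_size_m : float
        Cell edge length in metres (500 in the reference analysis).
    n_rows, n_cols : int
        Lattice shape; row index increases with y.
    marine_mask : (n_rows, n_cols) bool array
        True for water cells inside the study area.
    zone_label : (n_rows, n_cols) str array
        One of ``SZ``/``RZ``/``GUZ`` on marine cells, ``""`` elsewhere.
    zone_name : (n_rows, n_cols) str array, optional
        Individual zone identifier (e.g. ``SZ3``); ``""`` off-marine.
    """

    origin: tuple[float, float]
    cell_size_m: float
    n_rows: int
    n_cols: int
    marine_mask: np.ndarray
    zone_label: np.ndarray = None
    zone_name: np.ndarray = None

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise InvalidConfigError("cell_size_m must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidConfigError("grid must hold at least one cell")
        self.marine_mask = np.asarray(self.marine_mask, dtype=bool)
        if self.marine_mask.shape != (self.n_rows, self.n_cols):
            raise InvalidConfigError("marine_mask shape mismatch")
        if self.zone_label is None:
            self.zone_label = np.full((self.n_rows, self.n_cols), "", dtype="<U3")
        else:
            self.zone_label = np.asarray(self.zone_label, dtype="<U3")
        if self.zone_name is None:
            self.zone_name = np.full((self.n_rows, self.n_cols), "", dtype="<U8")
        else:
            self.zone_name = np.asarray(self.zone_name, dtype="<U8")

    # -- indexing ---------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row, col):
        """Row-major flat index."""
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_center(self, row, col):
        x0, y0 = self.origin
        cs = self.cell_size_m
        return (x0 + (np.asarray(col) + 0.5) * cs, y0 + (np.asarray(row) + 0.5) * cs)

    def cell_bounds(self, row, col):
        """(xmin, ymin, xmax, ymax) of one cell."""
        x0, y0 = self.origin
        cs = self.cell_size_m
        return (x0 + col * cs, y0 + row * cs, x0 + (col + 1) * cs, y0 + (row + 1) * cs)

    def point_to_rowcol(self, x, y):
        """Half-open convention: a point on a shared edge belongs to the
        cell whose interval contains it (floor indexing)."""
        x0, y0 = self.origin
        cs = self.cell_size_m
        col = np.floor((np.asarray(x) - x0) / cs).astype(int)
        row = np.floor((np.asarray(y) - y0) / cs).astype(int)
        return row, col

    def in_bounds(self, row, col):
        return (
            (np.asarray(row) >= 0)
            & (np.asarray(row) < self.n_rows)
            & (np.asarray(col) >= 0)
            & (np.asarray(col) < self.n_cols)
        )

    # -- convenience ------------------------------------------------------

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def marine_cell_ids(self) -> np.ndarray:
        rows, cols = np.nonzero(self.marine_mask)
        return np.sort(self.cell_id(rows, cols))

    def centers(self):
        """(X, Y) arrays of all cell centres, grid-shaped."""
        x0, y0 = self.origin
        cs = self.cell_size_m
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = y0 + (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def equal_geometry(self, other: "GridSpec") -> bool:
        return (
            self.origin == other.origin
            and self.cell_size_m == other.cell_size_m
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )
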