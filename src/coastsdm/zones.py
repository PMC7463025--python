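"""Occurrence bands, management-zone summaries and the sanctuary overlap test.

The ensemble probability surface is classified into Low / Medium / High
occurrence bands, summarised per sanctuary zone (and combined / outside),
and the count of High cells inside sanctuary (no-take) zones is compared
with its distribution when the same number of High cells is scattered
uniformly over the marine lattice (a permutation test; the exact null is
hypergeometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceBands",
    "RandTestResult",
    "classify_occurrence",
    "band_proportions",
    "zone_summary",
    "randomization_test",
]

BAND_LABELS = ("Low", "Medium", "High")


@dataclass(frozen=True)
class OccurrenceBands:
    """Band edges: Low = [0, low_max], Medium = (low_max, high_min],
    High = (high_min, 1] — half-open so the partition is total."""

    low_max: float = 0.3
    high_min: float = 0.6

    def __post_init__(self):
        if not (0 < self.low_max < self.high_min < 1):
            raise ValueError("require 0 < low_max < high_min < 1")


@dataclass
class RandTestResult:
    """Sanctuary overlap randomization test outcome."""

    observed_index: int
    null_distribution: np.ndarray
    p_value: float
    seed: int
    n_permutations: int

    def to_dict(self):
        return {
            "observed_index": int(self.observed_index),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "null_mean": float(np.mean(self.null_distribution)),
            "null_sd": float(np.std(self.null_distribution)),
        }


def classify_occurrence(probability, bands: OccurrenceBands | None = None):
    """Band label per cell; NaN cells map to an empty label."""
    bands = bands or OccurrenceBands()
    p = np.asarray(probability, dtype=float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.full(p.shape, "", dtype="<U6")
    finite = np.isfinite(p)
    out[finite & (p <= bands.low_max)] = "Low"
    out[finite & (p > bands.low_max) & (p <= bands.high_min)] = "Medium"
    out[finite & (p > bands.high_min)] = "High"
    return out


def band_proportions(probability_grid, grid: GridSpec, bands=None) -> pd.DataFrame:
    """Percent of marine cells per band, overall and inside sanctuary zones."""
    labels = classify_occurrence(probability_grid, bands)
    marine = grid.marine_mask & (labels != "")
    sz = marine & (grid.zone_label == "SZ")
    rows = []
    for band in BAND_LABELS:
        rows.append(
            {
                "band": band,
                "study_area_pct": 100.0 * np.sum(marine & (labels == band)) / max(marine.sum(), 1),
                "sanctuary_pct": 100.0 * np.sum(sz & (labels == band)) / max(sz.sum(), 1),
            }
        )
    return pd.DataFrame(rows)


def _stats_row(values: np.ndarray, cell_area_km2: float) -> dict:
    n = len(values)
    if n == 0:
        return {
            "area_km2": 0.0, "n_cells": 0, "mean": np.nan, "sd": np.nan,
            "median": np.nan, "min": np.nan, "max": np.nan,
        }
    return {
        "area_km2": n * cell_area_km2,
        "n_cells": n,
        "mean": float(np.mean(values)),
        "sd": float(np.std(values)),
        "median": float(np.median(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def zone_summary(probability_grid, grid: GridSpec) -> pd.DataFrame:
    """Occurrence-probability statistics per sanctuary zone.

    One row per individual sanctuary zone, a combined sanctuary row, and
    an outside row (recreation + general-use cells). Zones with zero
    cells are emitted with n = 0 and undefined statistics (logged).
    """
    prob = np.asarray(probability_grid, dtype=float)
    marine = grid.marine_mask & np.isfinite(prob)
    cell_km2 = grid.cell_area_m2 / 1e6
    rows = []
    sz_names = sorted(
        {n for n in np.unique(grid.zone_name[grid.zone_label == "SZ"]) if n}
    )
    for name in sz_names:
        mask = marine & (grid.zone_name == name)
        row = _stats_row(prob[mask], cell_km2)
        if row["n_cells"] == 0:
            logger.warning("sanctuary zone %s holds no marine cells", name)
        rows.append({"zone": name, **row})
    combined = marine & (grid.zone_label == "SZ")
    rows.append({"zone": "Combined SZ", **_stats_row(prob[combined], cell_km2)})
    outside = marine & np.isin(grid.zone_label, ("RZ", "GUZ"))
    rows.append({"zone": "Outside (RZ & GUZ)", **_stats_row(prob[outside], cell_km2)})
    return pd.DataFrame(rows)


def randomization_test(
    high_mask,
    sanctuary_mask,
    marine_mask,
    n_permutations: int = 5_000,
    seed: int = 0,
) -> RandTestResult:
    """Do High-occurrence cells fall inside sanctuary zones more often
    than expected by chance?

    The observed index counts High cells inside sanctuary zones. Each
    permutation relocates the k High cells uniformly at random (without
    replacement) over the N marine cells and recounts; the one-sided
    upper-tail p-value is the proportion of permuted indices >= observed.
    """
    high = np.asarray(high_mask, dtype=bool).ravel()
    sz = np.asarray(sanctuary_mask, dtype=bool).ravel()
    marine = np.asarray(marine_mask, dtype=bool).ravel()
    if not sz.any():
        raise ValueError("sanctuary mask is empty")
    if (high & ~marine).any() or (sz & ~marine).any():
        raise ValueError("high/sanctuary cells must be marine cells")

    k = int(high.sum())
    observed = int((high & sz).sum())
    rng = np.random.default_rng(seed)
    if k == 0:
        logger.warning("zero High cells; randomization test is trivial (p = 1)")
        null = np.zeros(n_permutations, dtype=int)
        return RandTestResult(0, null, 1.0, seed, n_permutations)

    sz_flags = sz[marine]
    n_marine = int(marine.sum())
    # vectorised permutations: k smallest random keys per row select cells
    null = np.empty(n_permutations, dtype=int)
    batch = max(1, int(2e6 // n_marine))
    for start in range(0, n_permutations, batch):
        stop = min(start + batch, n_permutations)
        keys = rng.random((stop - start, n_marine))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[start:stop] = sz_flags[picks].sum(axis=1)
    p_value = float(np.mean(null >= observed))
    return RandTestResult(observed, null, p_value, seed, n_permutations)
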