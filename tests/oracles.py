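"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
pairwise enumeration for AUC, a heap-based Dijkstra for cost distance,
normal-equations VIF inside brute-force screening loops, direct linear
solves for kriging, and step-walking/rasterisation for geometry.
"""

from __future__ import annotations

import heapq

import numpy as np


def auc_enumeration(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant pair counting (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def vif_normal_equations(X: np.ndarray) -> np.ndarray:
    """VIF per column via normal equations with an explicit intercept."""
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta = np.linalg.solve(others.T @ others, others.T @ y)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _corr_abs(X):
    c = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(c, 0.0)
    return np.abs(c)


def vifcor_bruteforce(X: np.ndarray, names, r_threshold=0.7):
    """Re-implementation of the max-correlation exclusion loop."""
    names = list(names)
    X = X.copy()
    while X.shape[1] >= 2:
        c = _corr_abs(X)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= r_threshold:
            break
        vifs = vif_normal_equations(X)
        drop = i if vifs[i] > vifs[j] else j
        if vifs[i] == vifs[j]:
            drop = max(i, j)
        X = np.delete(X, drop, axis=1)
        del names[drop]
    return names


def vifstep_bruteforce(X: np.ndarray, names, vif_threshold=3.0):
    """Re-implementation of the max-VIF exclusion loop."""
    names = list(names)
    X = X.copy()
    while X.shape[1] >= 2:
        vifs = vif_normal_equations(X)
        j = int(np.argmax(vifs))
        ties = np.flatnonzero(vifs == vifs[j])
        j = int(ties.max())
        if vifs[j] <= vif_threshold:
            break
        X = np.delete(X, j, axis=1)
        del names[j]
    return names


def dijkstra_lattice(marine_mask: np.ndarray, sources, cell_size: float) -> np.ndarray:
    """Heap Dijkstra over an 8-connected lattice of marine cells.

    ``sources`` is an iterable of (row, col); returns a grid-shaped array
    of shortest-path distances (inf where unreachable, NaN off-marine).
    """
    n_rows, n_cols = marine_mask.shape
    dist = np.full((n_rows, n_cols), np.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    moves = [
        (dr, dc, cell_size * np.hypot(dr, dc))
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, w in moves:
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols and marine_mask[r2, c2]:
                nd = d + w
                if nd < dist[r2, c2]:
                    dist[r2, c2] = nd
                    heapq.heappush(heap, (nd, r2, c2))
    out = np.where(marine_mask, dist, np.nan)
    return out


def kriging_system_solve(sample_xy, values, target_xy, gamma):
    """Ordinary-kriging prediction by assembling the full system directly."""
    sample_xy = np.asarray(sample_xy, dtype=float)
    values = np.asarray(values, dtype=float)
    k = len(sample_xy)
    A = np.zeros((k + 1, k + 1))
    for i in range(k):
        for j in range(k):
            h = np.linalg.norm(sample_xy[i] - sample_xy[j])
            A[i, j] = 0.0 if h == 0 else gamma(h)
    A[k, :k] = 1.0
    A[:k, k] = 1.0
    b = np.zeros(k + 1)
    for i in range(k):
        b[i] = gamma(np.linalg.norm(sample_xy[i] - np.asarray(target_xy)))
    b[k] = 1.0
    w = np.linalg.solve(A, b)[:k]
    return float(w @ values), w


def polyline_step_lengths(lines, grid, step=1.0):
    """Per-cell track length by walking each polyline in tiny steps."""
    effort = np.zeros((grid.n_rows, grid.n_cols))
    for line in lines:
        arr = np.asarray(line, dtype=float)
        for i in range(len(arr) - 1):
            p, q = arr[i], arr[i + 1]
            seg = np.hypot(*(q - p))
            if seg == 0:
                continue
            n = max(int(np.ceil(seg / step)), 1)
            ts = (np.arange(n) + 0.5) / n
            pts = p + np.outer(ts, q - p)
            rows, cols = grid.point_to_rowcol(pts[:, 0], pts[:, 1])
            ok = grid.in_bounds(rows, cols)
            np.add.at(effort, (rows[ok], cols[ok]), seg / n)
    return effort


def hypergeom_tail(observed, n_marine, n_sz, k_high) -> float:
    """Exact Pr(X >= observed) for X ~ Hypergeom(N, m, k)."""
    from scipy.stats import hypergeom

    return float(hypergeom.sf(observed - 1, n_marine, n_sz, k_high))
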