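"""Dispersal limits from least-accumulative-cost analysis.

Landscape layers are reclassified into traversal-cost surfaces (1 =
highly permeable … 1,000,000 = insurmountable barrier), merged by cellwise
maximum, and a multi-source least-accumulative-cost distance is computed
from the occurrence cells over the 8-connected grid graph (ArcGIS Cost
Distance convention: step cost = mean of the two cell costs, ×√2 on
diagonals). The accumulated-cost surface is classified by Fisher–Jenks
natural breaks into seven classes; the lowest class is the dispersal
limit — the region the species is considered able to reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import AlignmentError, Grid
from .occurrences import OccurrenceSet

BARRIER_COST = 1_000_000.0
MIN_COST = 1.0


@dataclass
class CostSurface:
    """Per-cell traversal costs in [1, 1,000,000]."""

    grid: Grid
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ok = ~self.grid.nodata_mask
        v = self.grid.values[ok]
        if v.size and (v.min() < MIN_COST or v.max() > BARRIER_COST):
            raise ValueError("cost values must lie in [1, 1,000,000]")


@dataclass
class CostTable:
    """Ordered value-range→cost rules per layer (first matching rule wins;
    ranges are half-open ``[lo, hi)``)."""

    rules: dict[str, list[tuple[float, float, float]]]
    barrier_cost: float = BARRIER_COST


def reclassify(layer: Grid, rules: list[tuple[float, float, float]],
               name: str = "") -> CostSurface:
    """Map a layer through ordered (lo, hi, cost) rules."""
    ok = ~layer.nodata_mask
    vals = layer.values
    out = np.full(layer.shape, np.nan)
    unmatched = ok.copy()
    for lo, hi, cost in rules:
        if not MIN_COST <= cost <= BARRIER_COST:
            raise ValueError(f"rule cost {cost} outside [1, 1,000,000]")
        hit = unmatched & (vals >= lo) & (vals < hi)
        out[hit] = cost
        unmatched &= ~hit
    if unmatched.any():
        bad = vals[unmatched].flat[0]
        raise ValueError(
            f"value {bad} in layer {name or '<unnamed>'} not covered by any rule")
    out[~ok] = 0.0
    return CostSurface(grid=layer.copy_with(out), provenance=(name,) if name else ())


def suitability_cost(suitability: Grid, mtss: float,
                     top_cost: float = 1000.0) -> CostSurface:
    """Cost surface from a suitability map.

    Below the MTSS threshold: the barrier cost (unsuitable ⇒ impermeable).
    At or above it: costs decrease geometrically (log-linear in s) from
    ``top_cost`` at s = mtss down to 1 at s = 1, rounded to integers.
    """
    if not 0.0 < mtss < 1.0:
        raise ValueError("mtss must lie in (0, 1)")
    ok = ~suitability.nodata_mask
    s = suitability.values
    if s[ok].size and (s[ok].min() < 0 or s[ok].max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    u = np.clip((s - mtss) / (1.0 - mtss), 0.0, 1.0)
    cost = np.maximum(np.round(top_cost ** (1.0 - u)), MIN_COST)
    cost = np.where(s < mtss, BARRIER_COST, cost)
    cost[~ok] = 0.0
    return CostSurface(grid=suitability.copy_with(cost),
                       provenance=("suitability",))


def mosaic_max(surfaces: list[CostSurface]) -> CostSurface:
    """Cellwise maximum of aligned cost surfaces (conservative merge);
    nodata only where all inputs are nodata."""
    if not surfaces:
        raise ValueError("no surfaces to mosaic")
    ref = surfaces[0].grid
    for s in surfaces[1:]:
        if not ref.same_geometry(s.grid):
            raise AlignmentError("cost surfaces are not aligned")
    stackv = np.stack([np.where(s.grid.nodata_mask, -np.inf, s.grid.values)
                       for s in surfaces])
    out = stackv.max(axis=0)
    mask = ~np.isfinite(out)
    out[mask] = 0.0
    prov = tuple(p for s in surfaces for p in s.provenance)
    return CostSurface(grid=ref.copy_with(out, mask=mask), provenance=prov)


def cost_distance(cost: CostSurface, sources: OccurrenceSet) -> Grid:
    """Least accumulated cost from the source cells to every cell.

    Multi-source Dijkstra over the 8-connected grid graph; adjacent-cell
    step cost is the mean of the two cell costs, scaled by √2 for diagonal
    moves. Source cells get 0. Cells that are nodata or unreachable carry
    +∞ and are flagged in the output mask.
    """
    g = cost.grid
    ok = ~g.nodata_mask
    node_id = np.full(g.shape, -1, dtype=int)
    node_id[ok] = np.arange(int(ok.sum()))
    n_nodes = int(ok.sum())
    if n_nodes == 0:
        raise ValueError("cost surface has no valid cells")

    rows_i, cols_i, weights = [], [], []
    c = g.values
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        a_sl = (slice(0, g.n_rows - dr),
                slice(max(0, -dc), g.n_cols - max(0, dc)))
        b_sl = (slice(dr, g.n_rows),
                slice(max(0, dc), g.n_cols - max(0, -dc)))
        valid = ok[a_sl] & ok[b_sl]
        w = 0.5 * (c[a_sl] + c[b_sl])[valid]
        if diag:
            w = w * np.sqrt(2.0)
        rows_i.append(node_id[a_sl][valid])
        cols_i.append(node_id[b_sl][valid])
        weights.append(w)
    graph = coo_matrix(
        (np.concatenate(weights),
         (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n_nodes, n_nodes)).tocsr()

    src_nodes = set()
    for lo, la in zip(sources.lons, sources.lats):
        try:
            r, cidx = g.cell_of(lo, la)
        except IndexError:
            continue
        if ok[r, cidx]:
            src_nodes.add(int(node_id[r, cidx]))
    if not src_nodes:
        raise ValueError("no source point falls on a valid cost cell")
    dist = dijkstra(graph, directed=False, indices=sorted(src_nodes),
                    min_only=True)
    acc = np.full(g.shape, np.inf)
    acc[ok] = dist
    mask = ~np.isfinite(acc)
    return Grid(values=acc, nodata_mask=mask, origin=g.origin,
                resolution=g.resolution, crs_label=g.crs_label)


# -- Jenks natural breaks -------------------------------------------------

def _weighted_fisher_jenks(values: np.ndarray, weights: np.ndarray,
                           k: int) -> np.ndarray:
    """Exact Fisher–Jenks DP on (sorted unique value, weight) pairs.

    Minimizes total within-class weighted sum of squared deviations over
    contiguous partitions. Returns the index of the last element of each
    class. O(k·u²) for u unique values.
    """
    u = len(values)
    cw = np.concatenate([[0.0], np.cumsum(weights)])
    cwv = np.concatenate([[0.0], np.cumsum(weights * values)])
    cwv2 = np.concatenate([[0.0], np.cumsum(weights * values**2)])

    # dp[j] = best cost for values[0..j] with the current class count
    dp = (cwv2[1:] - cwv2[0]) - (cwv[1:] - cwv[0]) ** 2 / (cw[1:] - cw[0])
    back = np.zeros((k, u), dtype=int)
    for cls in range(1, k):
        new_dp = np.full(u, np.inf)
        for j in range(cls, u):
            i_arr = np.arange(cls, j + 1)  # last class = values[i..j]
            w = cw[j + 1] - cw[i_arr]
            s = cwv[j + 1] - cwv[i_arr]
            sse = (cwv2[j + 1] - cwv2[i_arr]) - s * s / w
            cand = dp[i_arr - 1] + sse
            a = int(np.argmin(cand))
            new_dp[j] = cand[a]
            back[cls, j] = i_arr[a]
        dp = new_dp
    bounds = np.empty(k, dtype=int)
    j = u - 1
    bounds[k - 1] = j
    for cls in range(k - 1, 0, -1):
        i = back[cls, j]
        bounds[cls - 1] = i - 1
        j = i - 1
    return bounds


def jenks_breaks(values: np.ndarray, n_classes: int,
                 max_exact: int = 100_000, max_exact_unique: int = 8192,
                 n_bins: int = 1024) -> np.ndarray:
    """Ascending class upper bounds of the Fisher–Jenks optimal partition.

    Runs the exact dynamic program on unique values (weighted by
    multiplicity). When there are more than ``max_exact`` finite values or
    more than ``max_exact_unique`` distinct ones, the data are first
    binned into ``n_bins`` equal-width bins and the DP runs on bin centers
    (documented approximation); returned bounds are always actual data
    values.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if n_classes < 1:
        raise ValueError("n_classes must be ≥ 1")
    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) < n_classes:
        raise ValueError(
            f"need ≥ {n_classes} distinct values, got {len(uniq)}")
    if (v.size > max_exact or len(uniq) > max_exact_unique) and len(uniq) > n_bins:
        hist, edges = np.histogram(v, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        vals_w, wts = centers[keep], hist[keep].astype(float)
        bounds = _weighted_fisher_jenks(vals_w, wts, n_classes)
        # map bin-center bounds back to the largest actual value in range
        upper = []
        for b in bounds[:-1]:
            edge = edges[1:][keep][b]
            upper.append(float(uniq[uniq <= edge + 1e-12].max()))
        upper.append(float(uniq.max()))
        return np.asarray(upper)
    bounds = _weighted_fisher_jenks(uniq, counts.astype(float), n_classes)
    return uniq[bounds].astype(float)


def jenks_objective(values: np.ndarray, breaks: np.ndarray) -> float:
    """Total within-class sum of squared deviations for given upper bounds."""
    v = np.sort(np.asarray(values, float))
    total = 0.0
    lo = -np.inf
    for hi in breaks:
        seg = v[(v > lo) & (v <= hi)]
        if seg.size:
            total += float(((seg - seg.mean()) ** 2).sum())
        lo = hi
    return total


@dataclass
class DispersalLimit:
    """Reachability mask: accumulated cost within the lowest Jenks class."""

    mask: np.ndarray
    grid: Grid = field(repr=False)
    class_breaks: np.ndarray = field(repr=False)
    threshold: float = 0.0

    @property
    def n_reachable(self) -> int:
        return int(self.mask.sum())


def limit_mask(accumulated: Grid, n_classes: int = 7) -> DispersalLimit:
    """Classify accumulated cost into ``n_classes`` Jenks classes and keep
    the lowest: the dispersal limit. Infinite/nodata cells are never
    reachable; source cells (cost 0) always are."""
    finite = ~accumulated.nodata_mask & np.isfinite(accumulated.values)
    if not finite.any():
        raise ValueError("no finite accumulated-cost cells")
    breaks = jenks_breaks(accumulated.values[finite], n_classes)
    threshold = float(breaks[0])
    mask = finite & (accumulated.values <= threshold)
    return DispersalLimit(mask=mask, grid=accumulated,
                          class_breaks=breaks, threshold=threshold)
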