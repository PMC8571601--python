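"""Binary habitat maps, dispersal-limited areas, and range-change statistics.

Continuous suitability is thresholded at the scenario's own MTSS (suitable
habitat) and at 0.8 (optimal habitat), cropped by the scenario's dispersal
limit, and converted to spheroid-geometry areas. Percent decreases are
reported against the current scenario; elevational shifts are tested with
two-sided Mann–Whitney U on the elevation values of the binary cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .dispersal import DispersalLimit
from .grid import AlignmentError, Grid, row_areas_km2

OPTIMAL_THRESHOLD = 0.8


def binarize(suitability: Grid, threshold: float,
             limit: DispersalLimit | None = None) -> np.ndarray:
    """Boolean map: suitability ≥ threshold, within the dispersal limit.

    Nodata cells are always False. ``limit=None`` skips the dispersal crop.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = (suitability.values >= threshold) & ~suitability.nodata_mask
    if limit is not None:
        if not suitability.same_geometry(limit.grid):
            raise AlignmentError("dispersal limit not aligned with suitability")
        out &= limit.mask
    return out


def area_km2(binary: np.ndarray, grid: Grid) -> float:
    """Total area of True cells, spherical-zone cell geometry."""
    binary = np.asarray(binary, bool)
    if binary.shape != grid.shape:
        raise AlignmentError("binary map shape does not match grid")
    per_row = row_areas_km2(grid)
    return float((binary.sum(axis=1) * per_row).sum())


def pct_decrease(current_km2: float, future_km2: float) -> float:
    """Percent decrease vs the current area, to one decimal."""
    if current_km2 <= 0:
        raise ValueError("current area must be positive")
    if future_km2 < 0:
        raise ValueError("future area must be non-negative")
    return round(100.0 * (current_km2 - future_km2) / current_km2, 1)


def elevation_shift_test(current_binary: np.ndarray, future_binary: np.ndarray,
                         elevation: Grid) -> tuple[float, float, int]:
    """Two-sided Mann–Whitney U between the elevation multisets of the two
    binary maps.

    Returns (W, p, direction): W is the U statistic of the future sample,
    direction the sign of (median future − median current). Exact
    enumeration for small tie-free samples, normal approximation with tie
    correction otherwise.
    """
    cur = np.asarray(current_binary, bool)
    fut = np.asarray(future_binary, bool)
    if cur.shape != elevation.shape or fut.shape != elevation.shape:
        raise AlignmentError("binary maps not aligned with elevation grid")
    cur &= ~elevation.nodata_mask
    fut &= ~elevation.nodata_mask
    x_cur = elevation.values[cur]
    x_fut = elevation.values[fut]
    if x_cur.size == 0 or x_fut.size == 0:
        raise ValueError("empty binary map in elevation-shift test")
    small = max(x_cur.size, x_fut.size) <= 50
    no_ties = np.unique(np.concatenate([x_cur, x_fut])).size == (
        x_cur.size + x_fut.size)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = mannwhitneyu(x_fut, x_cur, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x_fut) - np.median(x_cur)))
    return float(res.statistic), float(res.pvalue), direction


@dataclass
class ScenarioSummary:
    """Per-scenario areas, decreases, and elevational-shift test."""

    scenario_id: str
    suitable_area_km2: float
    optimal_area_km2: float
    pct_decrease_suitable: float
    pct_decrease_optimal: float
    elev_shift_W: float
    elev_shift_p: float
    elev_shift_direction: int


def summarize(scenarios: dict[str, Grid], limits: dict[str, DispersalLimit],
              mtss: dict[str, float], elevation: Grid,
              optimal_threshold: float = OPTIMAL_THRESHOLD,
              current_id: str = "current",
              ) -> tuple[list[ScenarioSummary], pd.DataFrame]:
    """Build the per-scenario range-change table.

    Each scenario is thresholded at its own MTSS and at the optimal
    threshold, cropped by its own dispersal limit; percent decreases are
    relative to ``current_id``. The Mann–Whitney test compares suitable-cell
    elevations of each future scenario against current (current row: NaN).
    Returns the summaries plus a CSV-ready table with columns
    scenario, suitable_km2, pct_dec_suitable, optimal_km2, pct_dec_optimal, W, p.
    """
    if current_id not in scenarios:
        raise ValueError(f"missing required scenario {current_id!r}")
    tpl = scenarios[current_id]
    cur_suit_bin = binarize(scenarios[current_id], mtss[current_id],
                            limits.get(current_id))
    cur_opt_bin = binarize(scenarios[current_id], optimal_threshold,
                           limits.get(current_id))
    cur_suit_area = area_km2(cur_suit_bin, tpl)
    cur_opt_area = area_km2(cur_opt_bin, tpl)

    summaries: list[ScenarioSummary] = []
    ids = [current_id] + [k for k in scenarios if k != current_id]
    for sid in ids:
        suit_bin = binarize(scenarios[sid], mtss[sid], limits.get(sid))
        opt_bin = binarize(scenarios[sid], optimal_threshold, limits.get(sid))
        s_area = area_km2(suit_bin, tpl)
        o_area = area_km2(opt_bin, tpl)
        if sid == current_id:
            w = p = float("nan")
            direction = 0
            dec_s = dec_o = 0.0
        else:
            dec_s = pct_decrease(cur_suit_area, s_area)
            dec_o = pct_decrease(cur_opt_area, o_area) if cur_opt_area > 0 else float("nan")
            if suit_bin.any():
                w, p, direction = elevation_shift_test(cur_suit_bin, suit_bin,
                                                       elevation)
            else:
                w = p = float("nan")
                direction = 0
        summaries.append(ScenarioSummary(
            scenario_id=sid, suitable_area_km2=s_area, optimal_area_km2=o_area,
            pct_decrease_suitable=dec_s, pct_decrease_optimal=dec_o,
            elev_shift_W=w, elev_shift_p=p, elev_shift_direction=direction))

    table = pd.DataFrame({
        "scenario": [s.scenario_id for s in summaries],
        "suitable_km2": [round(s.suitable_area_km2, 1) for s in summaries],
        "pct_dec_suitable": [s.pct_decrease_suitable for s in summaries],
        "optimal_km2": [round(s.optimal_area_km2, 1) for s in summaries],
        "pct_dec_optimal": [s.pct_decrease_optimal for s in summaries],
        "W": [s.elev_shift_W for s in summaries],
        "p": [s.elev_shift_p for s in summaries],
    })
    return summaries, table
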