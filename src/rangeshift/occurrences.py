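"""Occurrence records: spatial thinning, sampling-effort (bias) rasters,
and target-group background point selection.

Presence-only occurrence data carry the spatial footprint of survey effort.
The tools here reduce spatial clustering (one record per ~min-distance
neighborhood) and build a smoothed density raster from multi-species
"target group" records, from which background points are drawn so that the
background carries the same sampling bias as the presences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import EARTH_RADIUS_KM, Grid


@dataclass
class OccurrenceSet:
    """Point records: parallel lon/lat arrays plus optional species labels."""

    lons: np.ndarray
    lats: np.ndarray
    labels: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if self.lons.shape != self.lats.shape or self.lons.ndim != 1:
            raise ValueError("lons and lats must be 1-D and equal length")
        if np.any(~np.isfinite(self.lons)) or np.any(~np.isfinite(self.lats)):
            raise ValueError("NaN/inf coordinates are not allowed")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.lons.shape:
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.lons)

    def subset(self, idx: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(
            self.lons[idx], self.lats[idx],
            None if self.labels is None else self.labels[idx],
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"longitude": self.lons, "latitude": self.lats})
        if self.labels is not None:
            df.insert(0, "species", self.labels)
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, provenance: str = "") -> "OccurrenceSet":
        df = pd.read_csv(path)
        labels = df["species"].to_numpy() if "species" in df.columns else None
        return cls(df["longitude"].to_numpy(), df["latitude"].to_numpy(),
                   labels, provenance or path)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (broadcasting over array inputs)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_distances_km(occ: OccurrenceSet) -> np.ndarray:
    lon = occ.lons[:, None]
    lat = occ.lats[:, None]
    return haversine_km(lon, lat, occ.lons[None, :], occ.lats[None, :])


def _one_thin_pass(adj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One randomized thinning pass; returns boolean keep vector.

    Iteratively deletes a random member of the most-conflicted set until
    conflict-free, then greedily re-adds any dropped point that no longer
    conflicts, so the result is a maximal independent set.
    """
    n = adj.shape[0]
    keep = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(int)
    while True:
        deg_kept = np.where(keep, degree, -1)
        dmax = deg_kept.max()
        if dmax <= 0:
            break
        worst = np.flatnonzero(deg_kept == dmax)
        victim = rng.choice(worst)
        keep[victim] = False
        degree -= adj[victim]
    dropped = rng.permutation(np.flatnonzero(~keep))
    for i in dropped:
        if not np.any(adj[i] & keep):
            keep[i] = True
    return keep


def thin(occurrences: OccurrenceSet, min_distance_km: float, seed: int,
         n_repeats: int = 10) -> OccurrenceSet:
    """Spatially thin records so all pairwise great-circle distances are
    ≥ ``min_distance_km``.

    Runs ``n_repeats`` randomized passes and returns a pass retaining the
    most points (ties broken by seed order). Deterministic given seed.
    """
    if len(occurrences) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    d = pairwise_distances_km(occurrences)
    adj = d < min_distance_km
    np.fill_diagonal(adj, False)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(max(1, n_repeats)):
        keep = _one_thin_pass(adj.copy(), rng)
        if best is None or keep.sum() > best.sum():
            best = keep
    return occurrences.subset(np.flatnonzero(best))


@dataclass
class BiasRaster:
    """Non-negative sampling-intensity surface with its total mass."""

    grid: Grid
    normalization: float = field(init=False)

    def __post_init__(self) -> None:
        ok = ~self.grid.nodata_mask
        if np.any(self.grid.values[ok] < 0):
            raise ValueError("bias raster has negative values")
        self.normalization = float(self.grid.values[ok].sum())
        if not self.normalization > 0:
            raise ValueError("bias raster has zero total mass")


def density_raster(target_group: OccurrenceSet, template: Grid,
                   kernel_sigma_cells: float = 5.0) -> BiasRaster:
    """Per-cell record counts smoothed with a Gaussian kernel.

    ``kernel_sigma_cells = 0`` gives raw counts. Smoothing conserves total
    mass away from edges; nodata cells are zeroed after smoothing.
    """
    if len(target_group) == 0:
        raise ValueError("empty target group")
    counts = np.zeros(template.shape, dtype=float)
    for lo, la in zip(target_group.lons, target_group.lats):
        r, c = template.cell_of(lo, la)
        counts[r, c] += 1.0
    if kernel_sigma_cells > 0:
        counts = gaussian_filter(counts, sigma=kernel_sigma_cells,
                                 mode="constant", cval=0.0, truncate=6.0)
    counts[template.nodata_mask] = 0.0
    return BiasRaster(grid=template.copy_with(counts))


def sample_background(bias: BiasRaster, n: int, seed: int,
                      exclude_nodata: bool = True) -> OccurrenceSet:
    """Draw ``n`` distinct cells with probability ∝ bias value; one point
    per drawn cell, placed at the cell center."""
    g = bias.grid
    w = g.values.ravel().copy()
    if exclude_nodata:
        w[g.nodata_mask.ravel()] = 0.0
    pos = int((w > 0).sum())
    if pos < n:
        raise ValueError(
            f"requested {n} background cells but only {pos} have positive weight")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, replace=False, p=w / w.sum())
    rows, cols = np.unravel_index(np.sort(idx), g.shape)
    lons = g.west + (cols + 0.5) * g.resolution
    lats = g.north - (rows + 0.5) * g.resolution
    return OccurrenceSet(lons, lats, provenance="background")
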