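"""Synthetic mountain landscapes with known truth.

Generates spatially autocorrelated terrain (Gaussian-kernel-smoothed white
noise), climate layers tied to the terrain (temperature with an elevational
lapse rate and a latitudinal gradient, precipitation fields), forest-cover
layers, a known true-suitability surface (cloglog of a linear predictor of
the named layers), a spatial sampling-bias field shared by the focal
species and a multi-species target group, and warmed / precipitation-shifted
future layer stacks. Everything is reproducible from an explicit seed; no
hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, LayerStack
from .occurrences import OccurrenceSet

#: Layers whose values shift additively under warming scenarios.
TEMPERATURE_LAYERS = ("temp_mean",)
#: Layers scaled multiplicatively under precipitation scenarios.
PRECIPITATION_LAYERS = ("precip_wet", "precip_dry")

#: Predictors entering the true generating model (elevation is kept in the
#: stack for elevational analyses but acts only through slope/temperature).
DEFAULT_TRUE_BETA = {
    "slope": 2.0,
    "temp_mean": -1.8,
    "temp_seasonality": -0.7,
    "precip_wet": 1.0,
    "precip_dry": 1.2,
    "forest_mixed": 1.4,
    "forest_needle": 0.0,   # deliberately uninformative
    "isothermality": 0.0,   # deliberately uninformative
}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic landscape generator.

    Defaults emulate a temperate mountain peninsula at coarse (~0.025°)
    resolution: smoothed random terrain up to ~1,500 m, a 6.5 °C/km lapse
    rate, noisy but terrain-following climate, and a sampling-bias field
    favouring accessible (low, gently sloped) terrain.
    """

    smooth_sigma: float = 6.0          # cells; terrain autocorrelation scale
    elev_mean_m: float = 700.0
    elev_sd_m: float = 450.0
    lapse_rate_c_per_km: float = 6.5
    temp_base_c: float = 13.0
    temp_lat_gradient: float = -0.8    # °C per degree latitude northward
    temp_noise_sd: float = 0.3
    precip_wet_mean: float = 320.0     # mm, wettest-month-like
    precip_dry_mean: float = 35.0      # mm, driest-month-like
    intercept: float = -1.0            # of the true linear predictor
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    bias_smooth_sigma: float = 10.0
    bias_elev_weight: float = 0.8      # accessibility: bias against high ground
    sea_level_quantile: float = 0.12   # fraction of lowest terrain masked as sea
    origin: tuple[float, float] = (127.0, 41.0)
    resolution: float = 0.025


@dataclass
class SyntheticWorld:
    """A generated landscape plus its generating truth."""

    stack: LayerStack
    true_beta: dict[str, float]
    intercept: float
    bias_field: Grid
    seed: int
    params: GeneratorParams

    @property
    def predictor_names(self) -> list[str]:
        return [n for n in self.stack.names if n != "elevation"]

    def true_suitability(self) -> Grid:
        """cloglog(η_true) of the generating linear model, on valid cells.

        Layers are standardized over valid cells before applying the true
        coefficients, so the betas are on comparable scales.
        """
        ok = ~self.stack.union_nodata
        eta = np.full(self.stack.shape, np.nan)
        eta[ok] = self.intercept
        for name, b in self.true_beta.items():
            if b == 0.0:
                continue
            v = self.stack[name].values
            mu, sd = v[ok].mean(), v[ok].std()
            eta[ok] += b * (v[ok] - mu) / sd
        suit = np.zeros(self.stack.shape)
        suit[ok] = 1.0 - np.exp(-np.exp(eta[ok]))
        return self.stack.template.copy_with(suit)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (white noise at σ=0)."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma=sigma, mode="reflect")
        z = (z - z.mean()) / z.std()
    return z


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_world(n_rows: int, n_cols: int, seed: int,
               params: GeneratorParams | None = None) -> SyntheticWorld:
    """Generate a synthetic landscape; identical stacks for identical seeds."""
    if n_rows < 16 or n_cols < 16:
        raise ValueError("n_rows and n_cols must be ≥ 16")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)

    z_elev = _smooth_field(rng, shape, p.smooth_sigma)
    elevation = np.maximum(p.elev_mean_m + p.elev_sd_m * z_elev, 0.0)

    # sea mask from the lowest terrain fraction — an irregular coastline
    if p.sea_level_quantile > 0:
        sea = elevation <= np.quantile(elevation, p.sea_level_quantile)
    else:
        sea = np.zeros(shape, dtype=bool)

    # slope (degrees) from the finite-difference gradient of elevation;
    # cell size taken as ~resolution·111.32 km
    cell_m = p.resolution * 111_320.0
    gy, gx = np.gradient(elevation, cell_m)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope = slope * (35.0 / max(slope.max(), 1e-9))  # rescale into a 0–35° range

    lats = p.origin[1] - (np.arange(n_rows) + 0.5) * p.resolution
    lat_grid = np.repeat(lats[:, None], n_cols, axis=1)
    lat_anom = lat_grid - lat_grid.mean()

    temp_mean = (p.temp_base_c
                 - p.lapse_rate_c_per_km * elevation / 1000.0
                 + p.temp_lat_gradient * lat_anom
                 + p.temp_noise_sd * rng.standard_normal(shape))
    temp_seasonality = (1000.0 + 250.0 * _smooth_field(rng, shape, p.smooth_sigma)
                        + 40.0 * lat_anom)
    isothermality = 22.0 + 4.0 * _smooth_field(rng, shape, p.smooth_sigma)
    precip_wet = np.maximum(
        p.precip_wet_mean * (1.0 + 0.25 * _smooth_field(rng, shape, p.smooth_sigma))
        + 0.05 * (elevation - elevation.mean()), 1.0)
    precip_dry = np.maximum(
        p.precip_dry_mean * (1.0 + 0.30 * _smooth_field(rng, shape, p.smooth_sigma))
        + 0.008 * (elevation - elevation.mean()), 0.5)
    z_forest = _smooth_field(rng, shape, p.smooth_sigma)
    z_elev_std = (elevation - elevation.mean()) / max(elevation.std(), 1e-9)
    forest_mixed = 100.0 * _logistic(1.2 * z_forest + 0.8 * z_elev_std)
    # needleleaf cover is kept independent of the terrain so that, with a
    # zero true coefficient, it is fully uninformative about suitability
    forest_needle = 100.0 * _logistic(
        1.2 * _smooth_field(rng, shape, p.smooth_sigma))

    def grid(vals):
        return Grid(values=vals, nodata_mask=sea.copy(), origin=p.origin,
                    resolution=p.resolution)

    stack = LayerStack({
        "elevation": grid(elevation),
        "slope": grid(slope),
        "temp_mean": grid(temp_mean),
        "temp_seasonality": grid(temp_seasonality),
        "isothermality": grid(isothermality),
        "precip_wet": grid(precip_wet),
        "precip_dry": grid(precip_dry),
        "forest_needle": grid(forest_needle),
        "forest_mixed": grid(forest_mixed),
    })

    z_bias = _smooth_field(rng, shape, p.bias_smooth_sigma)
    bias = _logistic(1.5 * z_bias - p.bias_elev_weight * z_elev_std)
    bias[sea] = 0.0
    bias_field = grid(bias)

    return SyntheticWorld(stack=stack, true_beta=dict(p.true_beta),
                          intercept=p.intercept, bias_field=bias_field,
                          seed=seed, params=p)


def _draw_cells(weights: np.ndarray, n: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    flat = weights.ravel()
    pos = int((flat > 0).sum())
    if n > pos:
        raise ValueError(f"requested {n} cells but only {pos} have positive weight")
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    return np.unravel_index(idx, weights.shape)


def sample_occurrences(world: SyntheticWorld, n: int, bias_strength: float = 1.0,
                       seed: int = 0) -> OccurrenceSet:
    """Presence cells ∝ true suitability × bias^bias_strength, drawn without
    replacement; points jittered uniformly within the cell."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if bias_strength < 0:
        raise ValueError("bias_strength must be ≥ 0")
    rng = np.random.default_rng(seed)
    suit = world.true_suitability().values
    w = suit * np.power(world.bias_field.values, bias_strength)
    w[world.stack.union_nodata] = 0.0
    rows, cols = _draw_cells(w, n, rng)
    tpl = world.stack.template
    res = tpl.resolution
    lons = tpl.west + (cols + rng.uniform(0, 1, size=n)) * res
    lats = tpl.north - (rows + rng.uniform(0, 1, size=n)) * res
    return OccurrenceSet(lons, lats, provenance=f"synthetic seed={seed}")


def sample_target_group(world: SyntheticWorld, n_species: int = 8,
                        n_per_species: int = 120, bias_strength: float = 1.0,
                        seed: int = 0) -> OccurrenceSet:
    """Multi-species records sharing the world's sampling-bias field.

    Each species gets its own smooth habitat-preference field; records are
    drawn ∝ preference × bias^bias_strength, emulating related taxa
    recorded by the same surveys (use the same ``bias_strength`` as the
    focal species so the target group carries the same survey bias).
    """
    rng = np.random.default_rng(seed)
    tpl = world.stack.template
    res = tpl.resolution
    lons_all, lats_all, labels = [], [], []
    for s in range(n_species):
        pref = _logistic(1.5 * _smooth_field(rng, world.stack.shape,
                                             world.params.smooth_sigma))
        w = pref * np.power(world.bias_field.values, bias_strength)
        w[world.stack.union_nodata] = 0.0
        rows, cols = _draw_cells(w, n_per_species, rng)
        lons_all.append(tpl.west + (cols + rng.uniform(0, 1, n_per_species)) * res)
        lats_all.append(tpl.north - (rows + rng.uniform(0, 1, n_per_species)) * res)
        labels.append(np.full(n_per_species, f"species_{s:02d}"))
    return OccurrenceSet(np.concatenate(lons_all), np.concatenate(lats_all),
                         np.concatenate(labels), provenance="synthetic target group")


def make_scenario(world: SyntheticWorld, delta_t: float, precip_scale: float,
                  seed: int = 0, anomaly_sd: float = 0.0) -> LayerStack:
    """Future layer stack: temperature layers shifted by +delta_t,
    precipitation layers scaled by precip_scale, all other layers
    bit-identical to current.

    ``anomaly_sd > 0`` adds a smooth, seed-reproducible spatial anomaly to
    the temperature shift; the default (0) is exactly additive.
    """
    if precip_scale <= 0:
        raise ValueError("precip_scale must be positive")
    rng = np.random.default_rng(seed)
    layers: dict[str, Grid] = {}
    for name, g in world.stack.layers.items():
        if name in TEMPERATURE_LAYERS:
            shift = delta_t
            if anomaly_sd > 0:
                shift = delta_t + anomaly_sd * _smooth_field(
                    rng, g.shape, world.params.smooth_sigma)
            layers[name] = g.copy_with(g.values + shift)
        elif name in PRECIPITATION_LAYERS:
            layers[name] = g.copy_with(g.values * precip_scale)
        else:
            layers[name] = g
    return LayerStack(layers)
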