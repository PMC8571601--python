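"""End-to-end analysis runner.

One config file drives the whole chain: build (or load) a landscape and
occurrence data → spatial thinning → target-group density raster →
background sampling → optional variable screen → optional tuning grid →
final model fit → projection to future scenarios → dispersal limits via
cost distance → binary range-change summary. Every stochastic stage takes
a seed derived from the config; re-running the same config reproduces all
outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dispersal as dsp
from . import rangechange as rc
from .grid import Grid, LayerStack, read_grid, write_grid
from .maxent import FeatureSpec, SuitabilityModel, fit
from .occurrences import OccurrenceSet, density_raster, sample_background, thin
from .screen import screen_variables
from .synth import GeneratorParams, make_scenario, make_world, \
    sample_occurrences, sample_target_group
from .tuning import CV_SCHEMES, auc, mtss_threshold, omission10, partition, \
    results_table, select, tune


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated run settings (see ``examples/demo_run.toml``)."""

    raw: dict
    path: str | None = None

    seed: int = 0
    outdir: Path = Path("runs/out")
    # occurrence prep
    thin_km: float = 1.0
    thin_repeats: int = 10
    n_background: int = 10_000
    kernel_sigma_cells: float = 5.0
    # model
    features: str = "LQHPT"
    rm: float = 1.5
    optimal_threshold: float = 0.8
    n_jenks_classes: int = 7
    suitability_top_cost: float = 1000.0
    scenarios: dict[str, dict] = field(default_factory=dict)
    cost_rules: dict[str, list] = field(default_factory=dict)
    screen_cfg: dict | None = None
    tune_cfg: dict | None = None
    world_cfg: dict | None = None
    inputs_cfg: dict | None = None
    raster_format: str = "ascii_grid"

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw, path=path)

    @classmethod
    def from_dict(cls, raw: dict, path: str | None = None) -> "RunConfig":
        run = raw.get("run", {})
        cfg = cls(raw=raw, path=path)
        cfg.seed = int(run.get("seed", 0))
        cfg.outdir = Path(run.get("outdir", "runs/out"))
        occ = raw.get("occurrence_prep", {})
        cfg.thin_km = float(occ.get("thin_km", 1.0))
        cfg.thin_repeats = int(occ.get("thin_repeats", 10))
        cfg.n_background = int(occ.get("n_background", 10_000))
        cfg.kernel_sigma_cells = float(occ.get("kernel_sigma_cells", 5.0))
        model = raw.get("model", {})
        cfg.features = str(model.get("features", "LQHPT"))
        cfg.rm = float(model.get("rm", 1.5))
        cfg.optimal_threshold = float(model.get("optimal_threshold", 0.8))
        d = raw.get("dispersal", {})
        cfg.n_jenks_classes = int(d.get("n_classes", 7))
        cfg.suitability_top_cost = float(d.get("suitability_top_cost", 1000.0))
        cfg.cost_rules = {k: v for k, v in d.get("cost_rules", {}).items()}
        cfg.scenarios = dict(raw.get("scenarios", {}))
        cfg.screen_cfg = raw.get("screen") if raw.get("screen", {}).get(
            "enabled", False) else None
        cfg.tune_cfg = raw.get("tune") if raw.get("tune", {}).get(
            "enabled", False) else None
        cfg.world_cfg = raw.get("world")
        cfg.inputs_cfg = raw.get("inputs")
        cfg.raster_format = str(raw.get("output", {}).get(
            "raster_format", "ascii_grid"))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.world_cfg is None and self.inputs_cfg is None:
            raise ConfigError("config needs a [world] or an [inputs] section")
        if self.world_cfg is not None and self.inputs_cfg is not None:
            raise ConfigError("[world] and [inputs] are mutually exclusive")
        if self.inputs_cfg is not None:
            for key in ("layers", "occurrences", "target_group"):
                if key not in self.inputs_cfg:
                    raise ConfigError(f"[inputs] missing '{key}'")
            for name, p in self.inputs_cfg["layers"].items():
                if not Path(p).exists():
                    raise ConfigError(f"layer file for '{name}' not found: {p}")
            for key in ("occurrences", "target_group"):
                if not Path(self.inputs_cfg[key]).exists():
                    raise ConfigError(
                        f"{key} file not found: {self.inputs_cfg[key]}")
        if not self.scenarios and self.world_cfg is not None:
            raise ConfigError("config defines no future [scenarios]")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    """Returns (stack, occurrences, target_group, scenario_stacks, world)."""
    if cfg.world_cfg is not None:
        w = cfg.world_cfg
        gp_kwargs = {k: v for k, v in w.get("params", {}).items()}
        params = GeneratorParams(**gp_kwargs)
        world = make_world(int(w.get("rows", 120)), int(w.get("cols", 160)),
                           seed=cfg.seed, params=params)
        bias_strength = float(w.get("bias_strength", 1.0))
        occ = sample_occurrences(world, int(w.get("n_occurrences", 500)),
                                 bias_strength=bias_strength,
                                 seed=cfg.seed + 1)
        tg = sample_target_group(world,
                                 n_species=int(w.get("n_target_species", 8)),
                                 n_per_species=int(w.get("n_per_species", 120)),
                                 bias_strength=bias_strength,
                                 seed=cfg.seed + 2)
        scen = {sid: make_scenario(world, float(s.get("delta_t", 0.0)),
                                   float(s.get("precip_scale", 1.0)))
                for sid, s in cfg.scenarios.items()}
        return world.stack, occ, tg, scen, world
    inp = cfg.inputs_cfg
    stack = LayerStack({name: read_grid(p) for name, p in inp["layers"].items()})
    occ = OccurrenceSet.from_csv(inp["occurrences"])
    tg = OccurrenceSet.from_csv(inp["target_group"])
    scen = {}
    for sid, s in cfg.scenarios.items():
        scen[sid] = LayerStack({name: read_grid(p)
                                for name, p in s["layers"].items()})
    return stack, occ, tg, scen, None


def _landscape_cost_surfaces(stack: LayerStack,
                             cost_rules: dict[str, list]) -> list[dsp.CostSurface]:
    out = []
    for name, rules in cost_rules.items():
        parsed = [(float(lo), float(hi), float(c)) for lo, hi, c in rules]
        out.append(dsp.reclassify(stack[name], parsed, name=name))
    return out


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns a result dict and writes the run
    directory (models, rasters, tables, log)."""
    t0 = time.time()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                 "stages": {}}

    def stage(name):
        log["stages"][name] = round(time.time() - t0, 3)

    stack, occ_raw, tg_raw, scen_stacks, world = _load_inputs(config)
    stage("inputs")

    occ = thin(occ_raw, config.thin_km, seed=config.seed + 10,
               n_repeats=config.thin_repeats)
    tg = thin(tg_raw, config.thin_km, seed=config.seed + 11,
              n_repeats=config.thin_repeats)
    log["n_occurrences_raw"] = len(occ_raw)
    log["n_occurrences_thinned"] = len(occ)
    log["n_target_group_thinned"] = len(tg)
    stage("thin")

    bias = density_raster(tg, stack.template, config.kernel_sigma_cells)
    n_bg = min(config.n_background,
               int((bias.grid.values > 0).sum()) - 1)
    background = sample_background(bias, n_bg, seed=config.seed + 12)
    log["n_background"] = n_bg
    stage("background")

    var_names = [n for n in stack.names if n != "elevation"]
    if config.screen_cfg:
        report = screen_variables(
            occ, background, stack,
            n_replicates=int(config.screen_cfg.get("n_replicates", 5)),
            threshold_pct=float(config.screen_cfg.get("threshold_pct", 3.0)),
            rho_cutoff=float(config.screen_cfg.get("rho_cutoff", 0.7)),
            seed=config.seed + 13, var_names=var_names)
        var_names = report.final_variables
        report.to_json(outdir / "screen_report.json")
    log["variables"] = var_names
    stage("screen")

    features, rm = config.features, config.rm
    if config.tune_cfg:
        tc = config.tune_cfg
        results = tune(occ, background, stack,
                       feature_grid=tuple(tc.get("feature_grid",
                                                 ("L", "LQH", "LQHPT"))),
                       rm_grid=tuple(tc.get("rm_grid", (0.5, 1.5, 4.0))),
                       schemes=tuple(tc.get("schemes", CV_SCHEMES)),
                       seed=config.seed + 14, var_names=var_names)
        results_table(results).to_csv(outdir / "candidates.csv", index=False)
        best = select(results, tc.get("criterion", "aicc_min"))
        features, rm = best.feature_classes, best.rm
        log["tuned_features"] = features
        log["tuned_rm"] = rm
    stage("tune")

    model = fit(occ, background, stack, spec=FeatureSpec.from_string(features),
                rm=rm, var_names=var_names)
    model.to_json(outdir / "model.json")
    pres_scores = model.score_points(occ, stack)
    bg_scores = model.score_points(background, stack)
    mtss = mtss_threshold(pres_scores, bg_scores)
    log["mtss"] = mtss
    log["train_auc"] = auc(pres_scores, bg_scores)
    # 10-fold CV evaluation of the selected settings
    folds = partition(occ, "kfold10", seed=config.seed + 15)
    test_aucs, or10s = [], []
    for f in np.unique(folds):
        m = fit(occ.subset(folds != f), background, stack,
                spec=FeatureSpec.from_string(features), rm=rm,
                var_names=var_names)
        tr = m.score_points(occ.subset(folds != f), stack)
        te = m.score_points(occ.subset(folds == f), stack)
        bs = m.score_points(background, stack)
        test_aucs.append(auc(te, bs))
        or10s.append(omission10(tr, te))
    log["cv_test_auc_mean"] = float(np.mean(test_aucs))
    log["cv_test_auc_sd"] = float(np.std(test_aucs, ddof=1))
    log["cv_or10_mean"] = float(np.mean(or10s))
    log["auc_diff"] = log["train_auc"] - log["cv_test_auc_mean"]
    stage("fit")

    suit: dict[str, Grid] = {"current": model.predict(stack)}
    for sid, sstack in scen_stacks.items():
        suit[sid] = model.predict(sstack)
    for sid, g in suit.items():
        write_grid(g, outdir / f"suitability_{sid}.{_ext(config)}")
    stage("project")

    landscape_costs = _landscape_cost_surfaces(stack, config.cost_rules)
    mtss_by_scenario = {sid: mtss for sid in suit}
    limits: dict[str, dsp.DispersalLimit] = {}
    for sid, g in suit.items():
        pieces = landscape_costs + [
            dsp.suitability_cost(g, mtss, top_cost=config.suitability_top_cost)]
        cost = dsp.mosaic_max(pieces) if len(pieces) > 1 else pieces[0]
        acc = dsp.cost_distance(cost, occ)
        limits[sid] = dsp.limit_mask(acc, n_classes=config.n_jenks_classes)
    stage("dispersal")

    elevation = stack["elevation"] if "elevation" in stack else None
    if elevation is None:
        raise ConfigError("an 'elevation' layer is required for the summary")
    summaries, table = rc.summarize(suit, limits, mtss_by_scenario, elevation,
                                    optimal_threshold=config.optimal_threshold)
    table.to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump([s.__dict__ for s in summaries], fh, indent=1, default=float)
    stage("summarize")

    log["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return {"log": log, "model": model, "summaries": summaries,
            "table": table, "limits": limits, "suitability": suit,
            "world": world, "mtss": mtss}


def _ext(cfg: RunConfig) -> str:
    return "tif" if cfg.raster_format == "geotiff" else "asc"
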