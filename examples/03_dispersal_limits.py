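"""Derive dispersal limits from a cost-distance analysis.

Suitability below the MTSS threshold becomes an impermeable barrier
(cost 1,000,000); above it, cost falls log-linearly from 1,000 to 1.
The least accumulated cost from every occurrence cell is computed over
the 8-connected grid, classified into 7 Jenks natural-breaks classes,
and the lowest class is kept as the reachable region.
"""

import numpy as np

import rangeshift as rs

world = rs.make_world(100, 130, seed=42)
occ = rs.sample_occurrences(world, 300, bias_strength=1.5, seed=43)
tg = rs.sample_target_group(world, bias_strength=1.5, seed=44)
bias = rs.density_raster(rs.thin(tg, 1.0, seed=45), world.stack.template)
bg = rs.sample_background(bias, 3000, seed=46)
model = rs.fit(rs.thin(occ, 1.0, seed=47), bg, world.stack,
               spec="LQH", rm=1.0, var_names=world.predictor_names)

suit = model.predict(world.stack)
mtss = rs.mtss_threshold(model.score_points(occ, world.stack),
                         model.score_points(bg, world.stack))

# use only the southern half of the records as sources, mimicking a
# species whose confirmed range ends south of a contested frontier:
# suitable-looking terrain beyond dispersal reach is overprediction
south = occ.subset(occ.lats < np.median(occ.lats))
print(f"sources: {len(south)} southern records of {len(occ)}")

cost = rs.suitability_cost(suit, mtss)
ok = ~cost.grid.nodata_mask
n_barrier = int((cost.grid.values[ok] == rs.BARRIER_COST).sum())
print(f"cost surface: {n_barrier} barrier cells of {int(ok.sum())} "
      f"({100 * n_barrier / ok.sum():.0f}% of land below MTSS={mtss:.3f})")

acc = rs.cost_distance(cost, south)
limit = rs.limit_mask(acc, n_classes=7)
print("Jenks class upper bounds on accumulated cost:")
for i, b in enumerate(limit.class_breaks, 1):
    print(f"  class {i}: ≤ {b:,.1f}")
print(f"dispersal limit = class 1 (≤ {limit.threshold:,.1f}): "
      f"{limit.n_reachable} reachable cells "
      f"({100 * limit.n_reachable / ok.sum():.1f}% of land)")

suitable = rs.binarize(suit, mtss)
suitable_reachable = rs.binarize(suit, mtss, limit)
a_all = rs.area_km2(suitable, suit)
a_reach = rs.area_km2(suitable_reachable, suit)
print(f"suitable habitat: {a_all:,.1f} km² unconstrained, "
      f"{a_reach:,.1f} km² within dispersal limits "
      f"({100 * (1 - a_reach / a_all):.1f}% was unreachable overprediction)")
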