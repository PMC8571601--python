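"""Build a synthetic mountain landscape with known ground truth.

The generator produces spatially autocorrelated terrain, climate layers
tied to elevation (6.5 °C/km lapse rate), forest covers, a true
suitability surface (cloglog of a known linear model), and a sampling
bias field that favours accessible terrain.
"""

import numpy as np

import rangeshift as rs

world = rs.make_world(n_rows=100, n_cols=130, seed=42)
ok = ~world.stack.union_nodata

print(f"landscape: {world.stack.shape[0]}x{world.stack.shape[1]} cells, "
      f"{int(ok.sum())} on land")
for name in world.stack.names:
    v = world.stack[name].values[ok]
    print(f"  {name:18s} min {v.min():8.1f}  mean {v.mean():8.1f}  "
          f"max {v.max():8.1f}")

suit = world.true_suitability().values[ok]
print(f"true suitability: mean {suit.mean():.3f}, "
      f"{(suit >= 0.8).mean() * 100:.1f}% of land is optimal (≥0.8)")
print("true model coefficients (0 = uninformative):")
for k, b in world.true_beta.items():
    print(f"  {k:18s} {b:+.1f}")

# Biased occurrence sampling: survey effort concentrates in accessible
# terrain, so raw records misrepresent the niche.
occ = rs.sample_occurrences(world, n=400, bias_strength=2.0, seed=1)
print(f"\nsampled {len(occ)} presence records "
      f"(probability ∝ suitability × bias²)")
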