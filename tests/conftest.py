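import numpy as np
import pytest

import rangeshift as rs
from rangeshift.grid import Grid, LayerStack


@pytest.fixture(scope="session")
def small_world():
    """An 80×100 synthetic landscape shared by read-only tests."""
    return rs.make_world(80, 100, seed=7)


@pytest.fixture(scope="session")
def small_world_data(small_world):
    """Occurrences, target group, bias raster and background for the world."""
    world = small_world
    occ = rs.sample_occurrences(world, 300, bias_strength=1.5, seed=71)
    tg = rs.sample_target_group(world, n_species=6, n_per_species=120,
                                bias_strength=1.5, seed=72)
    bias = rs.density_raster(tg, world.stack.template, 5.0)
    bg = rs.sample_background(bias, 2500, seed=73)
    return {"occ": occ, "tg": tg, "bias": bias, "bg": bg}


def single_layer_stack(values, origin=(0.0, 10.0), resolution=0.1,
                       name="x", mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    g = Grid(values=values, nodata_mask=mask, origin=origin,
             resolution=resolution)
    return LayerStack({name: g})


def equator_grid(resolution=1.0, n_rows=1, n_cols=1):
    """Grid whose first row straddles the equator symmetrically."""
    vals = np.zeros((n_rows, n_cols))
    return Grid(values=vals, nodata_mask=np.zeros_like(vals, dtype=bool),
                origin=(0.0, resolution / 2.0), resolution=resolution)
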