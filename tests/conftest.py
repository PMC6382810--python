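import numpy as np
import pytest

from gogrow._rng import RngStreams
from gogrow.engine import SimConfig, World
from gogrow.mortality import MortalityRegime


@pytest.fixture
def rng():
    return RngStreams(12345)


def make_world(radius=200.0, boundary="open", regime=None, seed=0,
               phenotype=(40.0, 0.0), **cfg_kwargs):
    """Empty world for hand-built cell configurations."""
    cfg = SimConfig(duration_days=1.0, domain_radius=radius, boundary=boundary,
                    regime=regime if regime is not None else MortalityRegime.none(),
                    seed=seed, initial_phenotype=phenotype, **cfg_kwargs)
    return World(cfg)


@pytest.fixture
def world_factory():
    return make_world


def pairwise_min_distance(world):
    idx = world.live_indices(include_dying=True)
    if idx.size < 2:
        return np.inf
    p = world.pos[idx]
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    d2[np.diag_indices(idx.size)] = np.inf
    return float(np.sqrt(d2.min()))
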