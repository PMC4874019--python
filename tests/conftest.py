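import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ratepairs as rp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# orientation-tie warnings are expected in bulk runs; keep test output clean
logging.getLogger("ratepairs.contrasts").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cherry_tree():
    return rp.PhyloTree.from_newick_string("(A:0.1,B:0.2);")


@pytest.fixture
def three_tip_tree():
    return rp.PhyloTree.from_newick_string("((A:0.1,B:0.2):0.3,C:0.7);")


@pytest.fixture
def balanced_ultrametric():
    return rp.PhyloTree.from_newick_string(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


def make_traits(**kwargs):
    """Trait table from species -> (temperature, latitude) pairs."""
    import pandas as pd

    from ratepairs.tree_io import validate_traits

    rows = [
        dict(species_id=k, temperature=v[0], latitude=v[1])
        for k, v in kwargs.items()
    ]
    return validate_traits(pd.DataFrame(rows))


@pytest.fixture
def small_dataset():
    """100-tip null synthetic dataset shared by pipeline-level tests."""
    cfg = rp.SimConfig(n_tips=100, rng_seed=42)
    tree, traits, chrono = rp.generate_dataset(cfg)
    return tree, traits, chrono
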