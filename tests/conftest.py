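import numpy as np
import pandas as pd
import pytest

import treedab as td
from treedab.simulate import (
    SimulationSpec,
    choose_effect_nodes,
    random_multifurcating_tree,
    simulate_dataset,
)

FAST_SAMPLER = dict(num_samples=2500, burn_in=1000)


@pytest.fixture(scope="session")
def six_leaf_tree():
    return td.parse_newick("(T1,(T2,(T3,T4)N2)N1,(T5,T6)N3);")


@pytest.fixture(scope="session")
def sim_tree():
    return random_multifurcating_tree(10, depth=5, seed=3)


@pytest.fixture(scope="session")
def sim_truth(sim_tree):
    return choose_effect_nodes(sim_tree, seed=1)


@pytest.fixture(scope="session")
def strong_effect_sim(sim_tree, sim_truth):
    spec = SimulationSpec(p=10, n0=20, effect_size=0.9, seed=100)
    return simulate_dataset(spec, sim_truth, sim_tree)


@pytest.fixture(scope="session")
def fitted_estimator(sim_tree, strong_effect_sim):
    """One reduced-chain fit on a strong-effect dataset, shared across tests."""
    est = td.TreeCompositionalRegressor(
        tree=sim_tree, phi=5.0, reference=9, seed=0, **FAST_SAMPLER
    )
    est.fit(
        strong_effect_sim.X,
        pd.DataFrame(strong_effect_sim.Y, columns=strong_effect_sim.feature_names),
    )
    return est


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
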