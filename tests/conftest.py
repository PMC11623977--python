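import pytest

import ccw
from ccw.pipeline import compute_weighted_table


@pytest.fixture(scope="session")
def lung5_bundle():
    return ccw.fixture_lung5()


@pytest.fixture(scope="session")
def lung5_strategies():
    return ccw.fixture_strategies()


@pytest.fixture(scope="session")
def lung5_clones(lung5_bundle, lung5_strategies):
    clones = ccw.make_clones(lung5_bundle, lung5_strategies)
    return ccw.censor_clones(clones, lung5_bundle, lung5_strategies)


@pytest.fixture(scope="session")
def lung5_weighted(lung5_bundle, lung5_strategies):
    """Fixture table with unstabilized nonparametric IPCW weights."""
    spec = ccw.WeightModelSpec(implementation="nonparametric")
    table, _, _ = compute_weighted_table(lung5_bundle, lung5_strategies, spec)
    return table


@pytest.fixture(scope="session")
def sim_small():
    """A small confounded null cohort (binary frailty drives both processes)."""
    return ccw.simulate_cohort(ccw.SimulationParams(n=400, seed=42))


@pytest.fixture(scope="session")
def sim_strategies():
    from ccw.simulate import simulation_strategies

    return simulation_strategies(182, 365, "treatment")


@pytest.fixture(scope="session")
def z_weight_spec():
    return ccw.WeightModelSpec(
        implementation="nonparametric", denominator_covariates=("z",)
    )
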