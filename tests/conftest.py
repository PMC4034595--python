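import numpy as np
import pytest

import predmort as pm


def make_table(rows, schema="predation", traits=None):
    """Build a small validated table from (vessel, group, treatment, n, y) rows."""
    obs = [pm.TrialObservation(experiment=schema, vessel_id=v, group_label=g,
                               treatment=s, n_initial=n, n_dead=y)
           for v, g, s, n, y in rows]
    return pm.ExperimentTable(obs, traits=traits, schema=schema)


@pytest.fixture(scope="session")
def fixtures():
    return pm.packaged_fixtures()


@pytest.fixture(scope="session")
def predation_table():
    """Original-scale synthetic predation table (54 trials + 4 controls)."""
    table, truth = pm.simulate_predation_experiment(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def quick_config():
    return pm.ChainConfig(n_chains=3, n_steps=4_000, thin=10, burn_in=500, seed=3)


@pytest.fixture(scope="session")
def trait_samples(predation_table, quick_config):
    """A short but real trait-model fit, shared across tests."""
    table, _ = predation_table
    return pm.run_chains(table, "trait_reduced", config=quick_config)
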