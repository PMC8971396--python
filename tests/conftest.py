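import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import neuroscore as ns

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """Full-size synthetic gene universe under the default study conditions."""
    return ns.simulate_genome(seed=1)


@pytest.fixture(scope="session")
def scored(genome):
    return ns.score_table(genome)


@pytest.fixture(scope="session")
def labeled(genome, scored):
    return pd.concat([genome, scored[["score", "percent", "high_scoring"]]], axis=1)


@pytest.fixture(scope="session")
def gene_map(genome):
    return ns.simulate_gene_models(
        len(genome), seed=1, symbols=genome["symbol"].tolist()
    )


@pytest.fixture(scope="session")
def model_index(gene_map):
    return ns.GeneModelIndex(gene_map[1])
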