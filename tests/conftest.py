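import numpy as np
import pandas as pd
import pytest

from omicsplex import (
    OmicsNetwork,
    RunConfig,
    SyntheticScenario,
    generate_drug_targets,
    generate_multiomics,
    run_pipeline,
    tiny_mh_example,
)


def make_network(layer_name, nodes, pairs, weight=1.0):
    """Convenience constructor for small hand-written networks."""
    edges = pd.DataFrame(
        [(a, b, weight, 1, weight, 0.01) for a, b in pairs],
        columns=["source", "target", "weight", "sign", "statistic", "adjusted_p"],
    )
    return OmicsNetwork(layer_name, nodes, edges)


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario()


@pytest.fixture(scope="session")
def synthetic_matrices(scenario):
    return generate_multiomics(scenario)


@pytest.fixture(scope="session")
def synthetic_drugs(scenario):
    return generate_drug_targets(scenario)


@pytest.fixture(scope="session")
def pipeline_result(scenario, synthetic_matrices, synthetic_drugs):
    """Full default-scenario run shared across end-to-end tests."""
    config = RunConfig(correlation_methods={"proteome": "spearman"})
    return run_pipeline(synthetic_matrices, synthetic_drugs, config)


@pytest.fixture()
def tiny():
    return tiny_mh_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
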