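import pytest

from semix import RunConfig, SimulationParams, simulate_dataset
from semix.pipeline import run_all


@pytest.fixture(scope="session")
def tiny_params() -> SimulationParams:
    # small but with enough planted SE genes that every downstream stage
    # has a nontrivial SE set to work on
    return SimulationParams(
        n_genes=60, fraction_semi_extractable=0.15, mean_depth=150_000, rng_seed=7
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params):
    return simulate_dataset(tiny_params)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory, tiny_params):
    """Full pipeline on a small synthetic dataset, run once per session."""
    rundir = tmp_path_factory.mktemp("tiny_run")
    results = run_all(RunConfig(rng_seed=7), rundir, tiny_params)
    return rundir, results


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()
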