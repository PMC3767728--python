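"""Shared fixtures: configs, fixture population table, and cached base runs."""

import pytest

from bloodsim import ModelConfig, generate_fixture_population, run_simulation, stratify_and_summarize


@pytest.fixture(scope="session")
def base_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def fixture_table():
    return generate_fixture_population()


@pytest.fixture(scope="session")
def base_run_10k(base_config, fixture_table):
    """One 10,000-patient base-case run shared by the heavier suites."""
    return run_simulation(base_config, table=fixture_table, n_patients=10_000)


@pytest.fixture(scope="session")
def base_summaries_10k(base_run_10k, base_config):
    return stratify_and_summarize(base_run_10k, base_config)
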