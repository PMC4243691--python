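import pytest

import triplesulfur as ts


@pytest.fixture(scope="session")
def tables():
    """All packaged batch-experiment tables (default unit interpretation)."""
    return ts.make_fixture_tables()


@pytest.fixture(scope="session")
def table4(tables):
    return tables["table4"]


@pytest.fixture(scope="session")
def thio_study_config():
    """Thiosulfate-experiment study conditions for the synthetic generator."""

    def build(scenario=None, seed=0, **over):
        kw = dict(
            acceptor="thiosulfate",
            initial_acceptor_S=36.0,
            initial_cells=1.54e6,
            growth_rate=0.13,
            cs_rate=110.0,
            times=(0.0, 13.0, 19.0, 33.0, 40.0),
            scenario=scenario,
            seed=seed,
        )
        kw.update(over)
        return ts.SimConfig(**kw)

    return build
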