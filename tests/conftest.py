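import pytest

from pspcp import (
    FeatureConfig,
    default_property_table,
    easy_spec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def props():
    return default_property_table()


@pytest.fixture(scope="session")
def default_config(props):
    return FeatureConfig(w=0.15, lam=11, property_accessions=props.source_accessions)


@pytest.fixture(scope="session")
def easy_dataset():
    """Seed-pinned high-signal 3-class dataset (20 sequences per class)."""
    return generate_dataset(easy_spec(seed=0))
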