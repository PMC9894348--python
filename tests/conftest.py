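import pytest

from casefinder.synthetic_data import GeneratorConfig, generate_extract


@pytest.fixture(scope="session")
def small_extract():
    """Seeded synthetic extract of 800 patients with ground truth."""
    config = GeneratorConfig(n_patients=800, seed=7)
    extract, truth = generate_extract(config)
    return extract, truth, config


@pytest.fixture(scope="session")
def midsize_extract():
    """Larger seeded extract (n=2000) for the property suites."""
    config = GeneratorConfig(n_patients=2000, seed=42)
    extract, truth = generate_extract(config)
    return extract, truth, config
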