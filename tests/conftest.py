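import pytest

from matekin.synthetic import GeneratorConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """One reduced-scale synthetic study shared across tests."""
    return generate_study(GeneratorConfig.small(), seed=7)


@pytest.fixture(scope="session")
def medium_study():
    """Larger study for spatial-structure tests (more located males)."""
    cfg = GeneratorConfig.small(
        n_years=18, n_founder_females=30, n_founder_males=14, grid_cells=(30, 20)
    )
    return generate_study(cfg, seed=11)
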