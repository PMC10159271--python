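import pytest

from vcgsim.synthetic import (
    default_mixture_spec,
    generate_hcd_pool,
    generate_legacy_study,
    legacy_group_specs,
)

# canonical seed for fixtures shared across the suite
SEED = 1


@pytest.fixture(scope="session")
def default_pool():
    """Calibrated confounded pool: 30 studies x 10 animals, CO2 share 0.44."""
    return generate_hcd_pool(default_mixture_spec(), seed=SEED)


@pytest.fixture(scope="session")
def legacy_study():
    """Legacy-study fixture with exact group moments (control first)."""
    return generate_legacy_study(legacy_group_specs(), seed=SEED)
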