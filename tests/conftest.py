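import numpy as np
import pytest

from fpconn.synthetic import make_species_spec


@pytest.fixture
def base_fingerprint():
    """A planted 8-target fingerprint with distinct values (canonical order)."""
    return np.array([0.5, 0.2, 0.4, 0.1, 0.3, 0.25, 0.15, 0.35])


@pytest.fixture
def small_spec(base_fingerprint):
    """One seed, five runs, short scans: fast end-to-end material."""
    return make_species_spec(
        "testspecies",
        {"SEED": base_fingerprint},
        n_volumes=300,
        runs_per_animal=5,
        rng_seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
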