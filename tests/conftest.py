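import numpy as np
import pytest

from scnlight.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-neuron cohort at default noise/gain (324 traces)."""
    return generate_cohort(CohortConfig(n_neurons=12, seed=3))


@pytest.fixture(scope="session")
def small_cohort_z(small_cohort):
    from scnlight.pipeline import normalize_cohort

    return normalize_cohort(small_cohort)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: bleach + planted archetypes only."""
    cfg = CohortConfig(
        n_neurons=4,
        group_fractions=(0.0, 0.0, 1.0),
        noise_sd=0.0,
        transient_rate=0.0,
        shared_factor_weight=0.0,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
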