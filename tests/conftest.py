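import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from atlasnbs import (
    SyntheticCohortConfig,
    build_connectome,
    default_planted_edges,
    make_toy_atlas,
    simulate_cohort,
    stack_cohort,
)


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(12, (24, 24, 24), seed=7)


@pytest.fixture(scope="session")
def planted_edges(toy_atlas):
    return tuple(default_planted_edges(toy_atlas, k=6))


@pytest.fixture(scope="session")
def noiseless_cohort(toy_atlas, planted_edges):
    """Zero-noise cohort with a planted DRS effect on a 6-edge path."""
    config = SyntheticCohortConfig(
        planted_edges=planted_edges,
        effect_slope=-0.05,
        noise_sd=0.0,
        nuisance_slopes=(0.0, 0.0, 0.0),
        seed=11,
    )
    volumes, records, truth = simulate_cohort(toy_atlas, config)
    return volumes, records, truth


@pytest.fixture(scope="session")
def noisy_cohort(toy_atlas, planted_edges):
    config = SyntheticCohortConfig(planted_edges=planted_edges, seed=5)
    volumes, records, truth = simulate_cohort(toy_atlas, config)
    return volumes, records, truth


@pytest.fixture(scope="session")
def noisy_stack(toy_atlas, noisy_cohort):
    volumes, records, _ = noisy_cohort
    conns = [
        build_connectome(v, toy_atlas, subject_id=s)
        for v, s in zip(volumes, records["subject"])
    ]
    return stack_cohort(conns)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
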