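import dataclasses

import numpy as np
import pytest

import liverspare as ls


def small_phantom_config(**overrides) -> ls.PhantomConfig:
    """A fast low-resolution phantom used by unit tests."""
    kwargs = dict(
        grid_shape=(64, 64, 16),
        spacing_mm=(2.2, 2.2, 8.0),
        gtv_radius_mm=8.0,
        gtv_offset_mm=(4.0, 3.0, -8.0),
        seed=7,
    )
    kwargs.update(overrides)
    return ls.PhantomConfig(**kwargs)


def small_run_config(**overrides) -> ls.RunConfig:
    """A reduced cohort configuration for fast end-to-end unit tests."""
    kwargs = dict(
        n_patients=1,
        base_seed=11,
        phantom=small_phantom_config(),
        n_beams=7,
        max_iter=60,
        sparing_max_steps=4,
    )
    kwargs.update(overrides)
    return ls.RunConfig(**kwargs)


@pytest.fixture(scope="session")
def default_cohort() -> ls.CohortResult:
    """The full 10-phantom comparison at the default study conditions.

    Shared across acceptance tests; functional fractions span 0.2-0.85 and
    tumour radii 8-20 mm, planning grid 64 x 64 x 24.
    """
    return ls.run_cohort(ls.RunConfig(n_patients=10, base_seed=1))


@pytest.fixture
def small_patient():
    return ls.generate_patient(small_phantom_config())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
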