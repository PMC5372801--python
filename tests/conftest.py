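import numpy as np
import pytest

from compartpls import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A desk-scale cohort: 12^3 grid, 8+8 subjects, two small ventricles."""
    defaults = dict(
        n_patients=8,
        n_controls=8,
        grid_shape=(12, 12, 12),
        ventricle_seeds=((4, 6, 6), (8, 6, 6)),
        ventricle_seed_radius=1,
        skeleton_fraction=0.25,
        seed=42,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20170329)
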