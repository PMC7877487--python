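import numpy as np
import pytest

import morphnet as mn


@pytest.fixture(scope="session")
def atlas116():
    """Full 116-region parcellation on the default desk-scale grid."""
    return mn.generate_atlas((48, 48, 48), n_regions=116, seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    """Cheap 12-region parcellation for unit tests."""
    return mn.generate_atlas((20, 20, 20), n_regions=12, seed=3)


@pytest.fixture(scope="session")
def one_subject(atlas116):
    gm_maps, pheno = mn.simulate_cohort(
        atlas116, 1, 1, mn.default_effect(0.0), seed=11
    )
    return gm_maps[0]


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    effect = mn.default_effect(1.0, n_regions=12)
    gm_maps, pheno = mn.simulate_cohort(small_atlas, 8, 8, effect, seed=5)
    return gm_maps, pheno


def random_density(rng, grid_size=16):
    grid = np.linspace(0.0, 1.0, grid_size)
    probs = rng.dirichlet(np.ones(grid_size)) + 1e-6
    probs /= probs.sum()
    return mn.DensityProfile(grid=grid, probs=probs)
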