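import numpy as np
import pytest

import designmap as dm


@pytest.fixture(scope="session")
def opss_world():
    """A 40x40 blocked population with known truth, sampled under OPSS."""
    pop, truth = dm.simulate_population(nx=40, ny=40, n_blocks=40,
                                        p_predictors=6, seed=101)
    design = dm.design_from_population(pop, "OPSS")
    pop_s = dm.sample_and_observe(pop, truth, design,
                                  np.random.default_rng(202))
    return pop, truth, design, pop_s


@pytest.fixture(scope="session")
def fitted(opss_world):
    _, _, design, pop_s = opss_world
    model = dm.PixelMapModel(pop_s, design=design)
    return model, model.fit()


@pytest.fixture()
def small_pop():
    """Tiny 6x4 population, 4 blocks of 6, no predictors."""
    pop, truth = dm.simulate_population(nx=6, ny=4, n_blocks=4,
                                        p_predictors=0, seed=7)
    return pop, truth
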