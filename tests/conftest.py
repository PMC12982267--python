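import numpy as np
import pytest

from pollinet import synth


@pytest.fixture(scope="session")
def small_scenario():
    """A 3.2 km scenario small enough for per-test use."""
    return synth.SyntheticScenario(seed=11, extent=(3200.0, 3200.0), n_presence_per_species=150)


@pytest.fixture(scope="session")
def small_landscape(small_scenario):
    return synth.generate_landscape(small_scenario)


@pytest.fixture(scope="session")
def small_predictors(small_scenario, small_landscape):
    lc, el, pop = small_landscape
    return synth.true_predictors(small_scenario, lc, el, pop)


@pytest.fixture(scope="session")
def small_truth(small_scenario, small_landscape, small_predictors):
    lc, el, pop = small_landscape
    return {
        sp: synth.true_suitability(
            lc, el, pop, small_scenario.true_coefficients, sp, predictors=small_predictors
        )
        for sp in small_scenario.species
    }


def random_resistance_grid(rng, shape, lo=0.2, hi=5.0):
    from pollinet.grid import RasterGrid
    from pollinet.connectivity import ResistanceSurface

    r = rng.uniform(lo, hi, shape)
    return ResistanceSurface(RasterGrid(r, 1.0), 1e-3)
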