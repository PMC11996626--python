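import numpy as np
import pytest

import lanthascope as ls


@pytest.fixture(scope="session")
def species():
    return ls.load_constants()


@pytest.fixture(scope="session")
def recipe():
    return ls.seawater_recipe()


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic catalog shared by screen/classify/stats tests."""
    cfg = ls.SyntheticConfig(n_queries=120, n_samples=25, seed=11)
    return ls.simulate(cfg)


@pytest.fixture(scope="session")
def reference_sweep(species, recipe):
    """One DIC sweep at the canonical recipe, reused by the geochem tests."""
    grid = ls.dic_grid_for_ph_span(recipe, species, 7.4, 8.6, n=80)
    return ls.sweep_co2_constant_alkalinity(recipe, species, grid)


def random_protein(rng: np.random.Generator, length: int) -> str:
    from lanthascope.records import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
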