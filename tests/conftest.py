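import logging

import numpy as np
import pytest

import macrotol as mt

# library warnings (boundary caveats) are expected in simulation loops
logging.getLogger("macrotol").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return mt.SimulationConfig(
        n_strains=30,
        diets=("HPD", "HSD", "WD"),
        n_vials_per_diet=2,
        n_larvae_per_vial=30,
        n_variants=50,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return mt.simulate_survival_panel(small_config)


@pytest.fixture(scope="session")
def small_glmm_fits(small_panel):
    f1 = mt.fit_binomial_glmm(small_panel, random_slopes=False)
    f2 = mt.fit_binomial_glmm(small_panel, random_slopes=True)
    return f1, f2
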