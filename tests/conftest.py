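import pytest

import kolacross as kc


@pytest.fixture(scope="session")
def gx1():
    return kc.load_fixture("gx1_self")


@pytest.fixture(scope="session")
def mx2():
    return kc.load_fixture("mx2_self")


@pytest.fixture(scope="session")
def noise_free_trial():
    """Small simulated trial with noise off: expectations are exact."""
    params = kc.SimParams(seed=11, env_cv=0.0)
    pop = kc.make_population(params)
    design = kc.make_design(pop, n_single=25, n_double=6, seed=11)
    return kc.simulate_crossing_trial(pop, design, params)


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-parameter trial (env_cv=0.1) with singles and doubles."""
    params = kc.SimParams(seed=23)
    pop = kc.make_population(params)
    design = kc.make_design(pop, n_single=30, n_double=10, seed=23)
    return kc.simulate_crossing_trial(pop, design, params)
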