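import pytest

import ylandscape as yl


@pytest.fixture(scope="session")
def vocab():
    return yl.default_vocabulary()


@pytest.fixture(scope="session")
def small_demo():
    return yl.DemographyConfig.default(n_samples=600, seed=3)


@pytest.fixture(scope="session")
def small_tree(small_demo):
    return yl.simulate_tree(small_demo, depth=3, branching=2)


@pytest.fixture(scope="session")
def noiseless_cohort(small_tree, small_demo):
    return yl.simulate_cohort(small_tree, small_demo, yl.NoiseConfig.none())


@pytest.fixture(scope="session")
def noisy_cohort(small_tree, small_demo):
    return yl.simulate_cohort(small_tree, small_demo, yl.NoiseConfig())
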