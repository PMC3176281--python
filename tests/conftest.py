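import numpy as np
import pytest

from rootkern import (KernelFamily, KernelParams, RootModelParams, Stem,
                      StemMap, load_table1_fixture)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def random_map():
    """A reproducible 60-stem, 3-species map well inside its bounds."""
    rng = np.random.default_rng(42)
    stems = [Stem(f"s{i:03d}", f"sp{i % 3 + 1}",
                  float(rng.uniform(10, 90)), float(rng.uniform(10, 90)),
                  float(rng.uniform(1, 40)))
             for i in range(60)]
    return StemMap(stems, (0, 0, 100, 100))


@pytest.fixture
def exp_params():
    return RootModelParams(beta=1.5, family=KernelFamily.EXPONENTIAL,
                           kernel=KernelParams(alpha=5.0))
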