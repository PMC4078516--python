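import numpy as np
import pytest

from acvconf.synthetic import build_template, load_table1, load_table2


@pytest.fixture(scope="session")
def template():
    return build_template("N1")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240606)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).as_matrix()
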