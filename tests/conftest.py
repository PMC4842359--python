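import numpy as np
import pytest

from ckainit import SyntheticSpec, generate, tiny_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny():
    return tiny_fixture()


@pytest.fixture(scope="session")
def two_class_blobs():
    """Two Gaussian classes separated along feature 0 only (D=5, N=60)."""
    gen = np.random.default_rng(7)
    X = gen.standard_normal((60, 5))
    t = np.r_[np.ones(30), 2 * np.ones(30)].astype(int)
    X[t == 2, 0] += 3.0
    return X, t


@pytest.fixture(scope="session")
def small_synthetic():
    """Small three-class dataset with the default group schema scaled down."""
    spec = SyntheticSpec(
        group_sizes={"CV": 10, "SV": 8, "SA": 10, "TA": 10, "TS": 10},
        n_per_class=(40, 40, 40),
        informative_features=tuple(range(10, 16)),
        effect_size=2.0,
        seed=11,
    )
    return generate(spec)
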