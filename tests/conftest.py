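import numpy as np
import pytest
from hypothesis import settings

from normgp.datasets import (
    GeneratorConfig,
    make_all,
    make_dataset3,
    make_dataset4,
)
from normgp.kernels import RBF, Linear, Matern, RationalQuadratic

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


FIXED_KERNELS = {
    "linear": Linear(),
    "rbf": RBF(length_scale=1.0),
    "matern": Matern(length_scale=1.0, nu=1.5),
    "rq": RationalQuadratic(length_scale=1.0, alpha=1.0),
}


@pytest.fixture(scope="session")
def benchmarks():
    """All eight benchmark datasets at the default configuration (n=1000)."""
    return make_all(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def big_heteroskedastic():
    """Large-n Dataset-4-style data for consistency checks."""
    ds3 = make_dataset3(GeneratorConfig(n=100_000, seed=3))
    return make_dataset4(ds3)
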