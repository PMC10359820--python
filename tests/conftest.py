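import numpy as np
import pytest

from ksvasc.cohort import default_spec, generate_cohort
from ksvasc.trees import load_builtin_tree


@pytest.fixture(scope="session")
def t1():
    return load_builtin_tree("fixture_t1")


@pytest.fixture(scope="session")
def kaiser_tree():
    return load_builtin_tree("kaiser_reconstructed")


@pytest.fixture(scope="session")
def small_cohort(t1):
    """223 lesions under defaults, fixed seed — shared read-only fixture."""
    return generate_cohort(default_spec(seed=42), t1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
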