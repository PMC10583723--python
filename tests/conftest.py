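import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from batchalloc import AllocationProblem, derive_batch_sizes

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def problems(draw, max_treatments: int = 5, max_count: int = 8, max_batch: int = 5):
    """Random small allocation problems with near-equal batch sizes."""
    T = draw(st.integers(2, max_treatments))
    counts = draw(st.lists(st.integers(1, max_count), min_size=T, max_size=T))
    cap = draw(st.integers(2, max_batch))
    labels = [f"T{i + 1}" for i in range(T)]
    b = derive_batch_sizes(sum(counts), cap)
    return AllocationProblem(labels, counts, b)


@pytest.fixture
def setting_a() -> AllocationProblem:
    from batchalloc import SETTINGS

    return SETTINGS["A"]


@pytest.fixture
def tiny_problem() -> AllocationProblem:
    return AllocationProblem(["a", "b", "c"], [2, 2, 2], [2, 2, 2])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
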