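import numpy as np
import pytest

from adherclust import Cohort, StateSpace, Trajectory, default_state_space

# Three 12-visit sequences whose state proportions coincide but whose
# dynamics differ: the canonical demonstration that proportion-based
# summaries hide behavior that transition-based summaries expose.
I1 = tuple("999000001111")
I2 = tuple("901119100009")
I3 = tuple("910009001119")


@pytest.fixture(scope="session")
def space() -> StateSpace:
    return default_state_space()


@pytest.fixture(scope="session")
def worked_example(space):
    return [
        Trajectory("i1", I1),
        Trajectory("i2", I2),
        Trajectory("i3", I3),
    ]


@pytest.fixture(scope="session")
def worked_cohort(space, worked_example) -> Cohort:
    return Cohort(space, worked_example)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_cohort(
    rng: np.random.Generator, n: int, T: int, space: StateSpace
) -> Cohort:
    codes = rng.integers(0, space.n_states, size=(n, T))
    return Cohort.from_codes(space, codes)
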