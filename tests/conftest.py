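import numpy as np
import pytest
from hypothesis import settings

from eogadhd import TestConfig, build_schedule

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


#: Reduced test layout used where many simulations are needed: same
#: structure (3 stages, balanced directions), ~5x shorter.
SMALL_CONFIG = TestConfig(
    stage_durations=(11.0, 12.0, 12.0),
    direction_counts={"left": 8, "right": 8, "up": 6, "down": 6},
)

#: Minimal valid layout (12 events) for tests that only need bookkeeping.
TINY_CONFIG = TestConfig(
    stage_durations=(3.0, 3.0, 3.0),
    direction_counts={"left": 1, "right": 1, "up": 1, "down": 1},
)


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def small_schedule():
    return build_schedule(SMALL_CONFIG)


@pytest.fixture(scope="session")
def tiny_schedule():
    return build_schedule(TINY_CONFIG)


def kuhn_max_matching(compat: np.ndarray) -> int:
    """Exhaustive augmenting-path maximum bipartite matching (oracle)."""
    n_s, n_e = compat.shape
    match_of_event = [-1] * n_e

    def augment(i: int, seen: set[int]) -> bool:
        for j in range(n_e):
            if compat[i, j] and j not in seen:
                seen.add(j)
                if match_of_event[j] == -1 or augment(match_of_event[j], seen):
                    match_of_event[j] = i
                    return True
        return False

    return sum(augment(i, set()) for i in range(n_s))


@pytest.fixture(scope="session")
def matching_oracle():
    return kuhn_max_matching
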