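import numpy as np
import pytest

from tomsnn.gridworld import AgentState, GridWorld


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_world():
    """Wall-free world with two agents on opposite sides."""
    return GridWorld(
        walls=frozenset(),
        agents=[
            AgentState(position=(3, 0), goal=(3, 6), policy="reckless"),
            AgentState(position=(0, 3), goal=(6, 3), policy="cautious"),
        ],
    )


@pytest.fixture
def walled_world():
    """Vertical wall splitting the middle column, gap at the top."""
    walls = frozenset({(2, 3), (3, 3), (4, 3)})
    return GridWorld(
        walls=walls,
        agents=[
            AgentState(position=(3, 1), goal=(3, 5), policy="reckless"),
            AgentState(position=(3, 5), goal=(3, 1), policy="experienced"),
        ],
    )
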