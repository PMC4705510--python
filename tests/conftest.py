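import numpy as np
import pytest

from mucosim import agents as ag
from mucosim import engine as eng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_empty_state(width=10, height=10, cycles=1, seed=0, **overrides):
    """A small scenario with the six standard layers and no agents."""
    cfg = eng.ScenarioConfig(
        width=width, height=height, cycles=cycles, seed=seed, **overrides
    )
    return eng.init_scenario(cfg)


def place_agent(state, cell_type, cell_state, x, y, next_id=None, **kw):
    """Append a manually positioned agent to an initialized state."""
    aid = next_id if next_id is not None else len(state.agents)
    a = ag.CellAgent(
        id=aid, cell_type=cell_type, state=cell_state, x=x, y=y,
        compartment=state.space.compartment_of(x, y).name, **kw,
    )
    state.agents.append(a)
    return a


@pytest.fixture
def empty_state():
    return make_empty_state()
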