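import numpy as np
import pytest

from cellshove.lattice import Color, LatticeConfig, LatticeState


def make_state(grid01, colors=None):
    """Build a LatticeState from a small 0/1 occupancy array (x-major),
    defaulting occupants to green; ``colors`` may give an int8 array of codes
    1 (red) / 2 (green)."""
    grid01 = np.asarray(grid01)
    cfg = LatticeConfig(*grid01.shape)
    st = LatticeState(cfg, capacity=int(grid01.sum()) + 8)
    for x in range(cfg.Lx):
        for y in range(cfg.Ly):
            if grid01[x, y]:
                c = Color.GREEN if colors is None else Color(int(colors[x, y]))
                st.place((x + 1, y + 1), c)
    return st


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
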