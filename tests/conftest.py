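import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(lattice, cells):
    """Build a SimState by hand from {(q, r): species} (0=donor, 1=acceptor).

    Bonds can be added afterwards by assigning state.partner symmetrically.
    """
    from qbretsim.simulator import SimState

    W, H = lattice.width, lattice.height
    n = len(cells)
    grid = np.full(W * H, -1, dtype=np.int32)
    q = np.empty(n, dtype=np.int32)
    r = np.empty(n, dtype=np.int32)
    species = np.empty(n, dtype=np.int32)
    partner = np.full(n, -1, dtype=np.int32)
    for i, ((cq, cr), sp) in enumerate(cells.items()):
        grid[cq * H + cr] = i
        q[i], r[i], species[i] = cq, cr, sp
    return SimState(lattice=lattice, grid=grid, q=q, r=r,
                    species=species, partner=partner)
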