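import numpy as np
import pytest

from physarum_steiner import Lattice, SiteState, Topology
from physarum_steiner.cell_dynamics import repair_states


def lattice_from_ascii(rows, kind="bounded"):
    """Build a lattice from ASCII art: '.'=outside, 'o'=cytoplasm,
    '#'=membrane, 'X'=obstacle."""
    M = len(rows)
    assert all(len(r) == M for r in rows), "ascii lattice must be square"
    topo = Topology(kind, M)
    states = np.zeros((M, M), dtype=np.uint8)
    origin = np.zeros((M, M), dtype=np.int32)
    obstacle = np.zeros((M, M), dtype=bool)
    for y, row in enumerate(rows):
        for x, c in enumerate(row):
            if c == "o":
                states[y, x] = SiteState.CYTOPLASM
                origin[y, x] = 1
            elif c == "#":
                states[y, x] = SiteState.MEMBRANE
                origin[y, x] = 1
            elif c == "X":
                obstacle[y, x] = True
    return Lattice(topo, states, origin, obstacle)


def random_lattice(rng, M=8, kind="bounded", p_fill=0.45, obstacles=0.0):
    """Random repaired lattice for oracle comparisons."""
    topo = Topology(kind, M)
    states = (rng.random((M, M)) < p_fill).astype(np.uint8)
    obstacle = rng.random((M, M)) < obstacles
    states[obstacle] = 0
    origin = states.astype(np.int32)
    lat = Lattice(topo, states, origin, obstacle)
    repair_states(lat)
    return lat


@pytest.fixture
def np_rng():
    return np.random.default_rng(20260930)
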