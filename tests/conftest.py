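import numpy as np
import pytest

from streetgraph import make_cycle_graph, make_megastar_graph


@pytest.fixture
def tripartite():
    """The worked tripartite street graph: sizes [5, 3, 2], r = 1.5,
    mutants reproducing forward."""
    return make_cycle_graph([5, 3, 2], 1.5, "forward")


@pytest.fixture
def s0_single():
    """One initial mutant in the first partition."""
    return [1, 0, 0]


def random_street_graph(rng: np.random.Generator, max_states: int = 3000):
    """A random small cycle (k in 2..5, sizes <= 6) or megastar (m in 1..3,
    leaf length 1..2) with r in [0.5, 2], state space capped for exact
    enumeration."""
    while True:
        r = float(rng.uniform(0.5, 2.0))
        direction = "forward" if rng.random() < 0.5 else "backward"
        if rng.random() < 0.7:
            k = int(rng.integers(2, 6))
            sizes = rng.integers(1, 7, size=k).tolist()
            graph = make_cycle_graph(sizes, r, direction)
        else:
            m = int(rng.integers(1, 4))
            length = int(rng.integers(1, 3))
            center = int(rng.integers(1, 7))
            leaf = rng.integers(1, 4, size=length).tolist()
            graph = make_megastar_graph(center, leaf, m, r, direction)
        n_states = int(np.prod([s + 1 for s in graph.physical_sizes], dtype=np.int64))
        if n_states <= max_states:
            return graph


def random_interior_state(rng: np.random.Generator, graph, max_mutants: int = 3):
    """A transient initial state with a small number of mutants (1..max)."""
    sizes = graph.physical_sizes
    while True:
        state = [0] * len(sizes)
        for _ in range(int(rng.integers(1, max_mutants + 1))):
            p = int(rng.integers(0, len(sizes)))
            if state[p] < sizes[p]:
                state[p] += 1
        if 0 < sum(state) < graph.population_size:
            return state
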