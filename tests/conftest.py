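import numpy as np
import pytest

from cophylotrack import (EventCosts, Tanglegram, parse_newick,
                          random_binary_tree)


@pytest.fixture
def default_costs():
    """Zero-cost tracking, unit cost for everything else."""
    return EventCosts(0, 1, 1, 1, 1)


@pytest.fixture
def congruent3(default_costs):
    """Three-tip tanglegram with perfectly matching topologies."""
    host = parse_newick("((h1,h2),h3);")
    sym = parse_newick("((p1,p2),p3);")
    assoc = {f"p{i}": frozenset({f"h{i}"}) for i in (1, 2, 3)}
    return Tanglegram(host, sym, assoc)


def make_random_tanglegram(n_sym: int, n_host: int, seed: int) -> Tanglegram:
    """Random binary trees with uniform single-host tip mappings."""
    rng = np.random.default_rng(seed)
    host = random_binary_tree([f"h{i}" for i in range(n_host)], seed)
    sym = random_binary_tree([f"p{i}" for i in range(n_sym)], seed + 1)
    assoc = {f"p{i}": frozenset({f"h{int(rng.integers(n_host))}"})
             for i in range(n_sym)}
    return Tanglegram(host, sym, assoc)
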