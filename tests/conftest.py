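import warnings

import numpy as np
import pytest

import thermokin as tk
from thermokin.fixtures import ANTIPORTER_CONDITION, make_antiporter, make_dtpa, make_two_site


@pytest.fixture(scope="session")
def antiporter():
    return make_antiporter()


@pytest.fixture(scope="session")
def antiporter_rates(antiporter):
    with warnings.catch_warnings():
        # the leak edge's 31.6% relative error triggers the lognormal-validity
        # warning by design
        warnings.simplefilter("ignore", RuntimeWarning)
        return tk.consistent_rate_set(antiporter, ANTIPORTER_CONDITION)


@pytest.fixture(scope="session")
def two_site_independent():
    return make_two_site(7.0, 0.0)


@pytest.fixture(scope="session")
def dtpa():
    graph, groups = make_dtpa()
    return graph, groups


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def signed_cycle_sums(potentials):
    """Sum of consistent edge differences around every basis cycle."""
    import networkx as nx

    g = nx.Graph()
    for p in potentials.graph.processes:
        g.add_edge(p.source, p.target)
    sums = []
    for cycle in nx.cycle_basis(g):
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            total += potentials.dg(a, b)
        sums.append(total)
    return np.asarray(sums)
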