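import datetime as dt

import networkx as nx
import numpy as np
import pytest

from odnet.network_builder import DailyNetwork
from odnet.synthetic_data import random_weighted_network

A_DAY = dt.date(2020, 3, 11)


def make_net(edges, nodes=(), self_trips=None, date=A_DAY) -> DailyNetwork:
    """Build a DailyNetwork from (i, j, w) triples for tests."""
    g = nx.Graph()
    for i, j, w in edges:
        g.add_edge(i, j, weight=w)
    g.add_nodes_from(nodes)
    return DailyNetwork(date=date, graph=g, self_trips=dict(self_trips or {}))


def random_weighted_net(
    rng: np.random.Generator, n_max: int = 7, w_max: int = 9
) -> DailyNetwork:
    return random_weighted_network(rng, n_max=n_max, w_max=w_max)


@pytest.fixture
def triangle():
    return make_net([(1, 2, 1), (1, 3, 2), (2, 3, 3)])


@pytest.fixture
def path3():
    return make_net([(1, 2, 1), (2, 3, 1)])
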