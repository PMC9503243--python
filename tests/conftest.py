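import numpy as np
import pandas as pd
import pytest

from dbnsurv.bn import Cpt, Dag, DiscreteBayesNet
from dbnsurv.encoding import SurvivalRecord


@pytest.fixture
def toy_records():
    """Three subjects: event at 1, censored at 2, event at 3."""
    return [
        SurvivalRecord(1.0, 1),
        SurvivalRecord(2.0, 0),
        SurvivalRecord(3.0, 1),
    ]


def random_censored_dataset(rng, n=None):
    """(times, events) with ties, censoring, and at least one event."""
    if n is None:
        n = int(rng.integers(5, 501))
    times = np.round(rng.exponential(2.0, n), 2)
    events = (rng.random(n) < 0.7).astype(np.int8)
    if events.sum() == 0:
        events[int(rng.integers(n))] = 1
    return times, events


@pytest.fixture
def dataset_factory():
    return random_censored_dataset


def two_node_net(p_a=0.5, p_b_given_a1=0.9, p_b_given_a0=0.2):
    """A -> B with binary nodes."""
    dag = Dag(["A", "B"], [("A", "B")])
    cpts = {
        "A": Cpt("A", (), (0, 1), (), np.array([[1 - p_a, p_a]])),
        "B": Cpt(
            "B",
            ("A",),
            (0, 1),
            ((0, 1),),
            np.array(
                [[1 - p_b_given_a0, p_b_given_a0], [1 - p_b_given_a1, p_b_given_a1]]
            ),
        ),
    }
    return DiscreteBayesNet(dag, cpts)


@pytest.fixture
def simple_net():
    return two_node_net()


def random_net(rng, n_nodes=4, edge_prob=0.4, max_levels=2):
    """Random small discrete BN for enumeration oracles."""
    names = [f"V{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    dag = Dag(names, edges)
    cpts = {}
    for node in names:
        parents = dag.parents(node)
        r = int(rng.integers(2, max_levels + 1))
        levels = tuple(range(r))
        p_levels = tuple(cpts[p].levels for p in parents)
        q = int(np.prod([len(pl) for pl in p_levels])) if parents else 1
        table = rng.dirichlet(np.ones(r), size=q)
        cpts[node] = Cpt(node, parents, levels, p_levels, table)
    return DiscreteBayesNet(dag, cpts)


@pytest.fixture
def net_factory():
    return random_net


def frame_from_arrays(times, events, X=None):
    d = {"time": times, "event": events}
    if X is not None:
        for i in range(X.shape[1]):
            d[f"x{i + 1}"] = X[:, i]
    return pd.DataFrame(d)
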