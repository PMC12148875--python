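import numpy as np
import pytest

import painbn as pb
from painbn import calibration as cal
from painbn.model import Dag, VariableSpec
from painbn.parameters import Cpt, CptSet


@pytest.fixture(scope="session")
def truth():
    return pb.build_default_truth_network()


@pytest.fixture(scope="session")
def schema():
    return cal.default_schema()


@pytest.fixture(scope="session")
def cohort(truth):
    """One simulated cohort at the emulated sample size."""
    return pb.forward_sample(pb.GeneratorConfig(n=2400, seed=0))


@pytest.fixture(scope="session")
def big_cohort():
    return pb.forward_sample(pb.GeneratorConfig(n=100_000, seed=0))


@pytest.fixture
def chain_network():
    """a -> b with P(a=yes)=0.5, P(b=yes|a=yes)=0.8, P(b=yes|a=no)=0.2."""
    schema = (VariableSpec("a", ("no", "yes")), VariableSpec("b", ("no", "yes")))
    dag = Dag(["a", "b"], [("a", "b")])
    cpts = CptSet(
        [
            Cpt("a", (), (), np.array([[0.5, 0.5]])),
            Cpt("b", ("a",), (2,), np.array([[0.8, 0.2], [0.2, 0.8]])),
        ]
    )
    return schema, dag, cpts


def random_network(rng, n_nodes, p_arc=0.4):
    """A random binary-variable network with random CPTs (test helper)."""
    names = [f"v{i}" for i in range(n_nodes)]
    arcs = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_arc:
                arcs.append((names[i], names[j]))
    dag = Dag(names, arcs)
    cpts = {}
    for node in names:
        parents = dag.parents(node)
        cards = tuple(2 for _ in parents)
        n_cfg = 2 ** len(parents)
        p_yes = rng.uniform(0.05, 0.95, size=n_cfg)
        table = np.column_stack([1 - p_yes, p_yes])
        cpts[node] = Cpt(node, parents, cards, table)
    schema = tuple(VariableSpec(n, ("no", "yes")) for n in names)
    return schema, dag, CptSet(cpts)
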