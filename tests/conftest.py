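import numpy as np
import pytest

from netsynergy.knowledge_base import (
    DiseaseCharacterisation,
    DrugTargetProfile,
    EffectorState,
    InteractionEdge,
    Motive,
    ProteinNetwork,
    ProteinRef,
)


def make_network(triples, extra_nodes=()):
    """Build a network from (source, target, sign) triples."""
    edges = [
        InteractionEdge(ProteinRef(s), ProteinRef(t), sign)
        for s, t, sign in triples
    ]
    return ProteinNetwork(
        nodes=[ProteinRef(a) for a in extra_nodes], edges=edges
    )


def random_triples(rng, n_nodes, n_edges):
    """Random distinct (source, target, sign) triples, self-loops allowed."""
    names = [f"N{i}" for i in range(n_nodes)]
    seen, triples = set(), []
    while len(triples) < n_edges:
        s = names[rng.integers(n_nodes)]
        t = names[rng.integers(n_nodes)]
        sign = int(rng.choice([-1, 1]))
        if (s, t, sign) in seen:
            continue
        seen.add((s, t, sign))
        triples.append((s, t, sign))
    return triples


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def chain_network():
    """A -> B -> C activation chain with one inhibitory branch A -| D."""
    return make_network(
        [("A", "B", 1), ("B", "C", 1), ("A", "D", -1)]
    )


@pytest.fixture
def two_motive_disease():
    return DiseaseCharacterisation(
        "toy-disease",
        [
            Motive(
                "growth",
                [
                    EffectorState(ProteinRef("B"), +1),
                    EffectorState(ProteinRef("C"), +1),
                ],
            ),
            Motive(
                "survival",
                [
                    EffectorState(ProteinRef("C"), +1),
                    EffectorState(ProteinRef("D"), -1),
                ],
            ),
        ],
    )


@pytest.fixture
def simple_profile():
    return DrugTargetProfile("toy-drug", [(ProteinRef("A"), -1)])
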