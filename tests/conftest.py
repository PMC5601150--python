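"""Shared fixtures: tiny hand-checkable ontologies and generated datasets."""

import numpy as np
import pytest

from lncwalk.ontology import DiseaseOntology
from lncwalk.pipeline import network_from_dataset
from lncwalk.synthetic import PRESETS, generate


@pytest.fixture
def chain_ontology():
    """r -> a -> b: the three-term chain with hand-worked similarities."""
    return DiseaseOntology([("r", "a"), ("a", "b")])


@pytest.fixture
def diamond_ontology():
    """r -> {a, b} -> c: two equal-length paths from c to the root."""
    return DiseaseOntology([("r", "a"), ("r", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture(scope="session")
def small_dataset():
    return generate(PRESETS["small"])


@pytest.fixture(scope="session")
def small_network(small_dataset):
    return network_from_dataset(small_dataset)


@pytest.fixture(scope="session")
def default_network():
    """The standard planted benchmark (module structure, 10% noise)."""
    return network_from_dataset(generate(PRESETS["default"]))


def random_dag(rng: np.random.Generator, n_nodes: int, max_parents: int = 2):
    """Random layered DAG for oracle cross-checks (sparse enough that
    exhaustive path enumeration stays cheap)."""
    n_layers = int(rng.integers(2, 6))
    layers: list[list[str]] = [["n0"]]
    count = 1
    edges = []
    while count < n_nodes and len(layers) <= n_layers:
        width = int(rng.integers(1, max(2, n_nodes // n_layers + 1)))
        width = min(width, n_nodes - count)
        layer = [f"n{count + i}" for i in range(width)]
        prev = layers[-1]
        for node in layer:
            k = int(rng.integers(1, min(max_parents, len(prev)) + 1))
            for p in rng.choice(prev, size=k, replace=False):
                edges.append((str(p), node))
        layers.append(layer)
        count += width
    return DiseaseOntology(edges, terms=["n0"])


def enumerate_contribution_oracle(ont: DiseaseOntology, focus: str, w_e: float):
    """Path-enumeration oracle for the contribution weights.

    Walks every simple upward path from the focus and keeps, per reached
    ancestor, the maximum of ``w_e ** path_length`` — the definitionally
    equivalent closed form of the children-max recursion, computed without
    memoisation or topological ordering.
    """
    best = {focus: 1.0}

    def up(node: str, value: float) -> None:
        for parent in ont.parents(node):
            v = value * w_e
            if v > best.get(parent, -1.0):
                best[parent] = v
            up(parent, v)

    up(focus, 1.0)
    # w_e = 0 zeroes every proper ancestor but they remain ancestors
    for a in ont.ancestors(focus):
        best.setdefault(a, 0.0)
    return best


def pairwise_auc_oracle(scores, labels) -> float:
    """Exhaustive Mann-Whitney AUC: concordant pairs plus half the ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
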