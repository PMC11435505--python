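"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sensbn.bayesnet import CPTSet, NetworkSpec
from sensbn.synthetic import SimConfig, generate_dataset


# ---------------------------------------------------------------------------
# Brute-force joint-enumeration oracle for exact inference
# ---------------------------------------------------------------------------

def enumerate_posterior(spec: NetworkSpec, cpts: CPTSet,
                        evidence: dict[str, int], query: str) -> np.ndarray:
    """Posterior by summing the full joint over every variable assignment."""
    names = list(spec.nodes)
    cards = [spec.nodes[n] for n in names]
    out = np.zeros(spec.nodes[query])
    for assign in itertools.product(*(range(c) for c in cards)):
        state = dict(zip(names, assign))
        if any(state[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for node in names:
            idx = tuple(state[par] for par in cpts.parents[node]) + (state[node],)
            p *= cpts.tables[node][idx]
        out[state[query]] += p
    return out / out.sum()


def random_network(rng: np.random.Generator, max_nodes: int = 6,
                   max_card: int = 4) -> tuple[NetworkSpec, CPTSet]:
    """A random small DAG with random CPTs (edges respect a random order)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"X{i}" for i in range(n)]
    cards = {nm: int(rng.integers(2, max_card + 1)) for nm in names}
    order = list(rng.permutation(names))
    edges = []
    for j, child in enumerate(order[1:], start=1):
        for parent in order[:j]:
            if rng.random() < 0.4:
                edges.append((parent, child))
    spec = NetworkSpec(nodes=cards, edges=edges, target=order[-1])
    parents = {nm: spec.parents(nm) for nm in names}
    tables = {}
    for nm in names:
        shape = tuple(cards[p] for p in parents[nm]) + (cards[nm],)
        t = rng.random(shape) + 0.05
        tables[nm] = t / t.sum(axis=-1, keepdims=True)
    return spec, CPTSet(parents=parents, tables=tables)


# ---------------------------------------------------------------------------
# Synthetic datasets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noiseless_train():
    return generate_dataset(SimConfig(n=400, seed=11, noiseless=True))


@pytest.fixture(scope="session")
def noiseless_test():
    return generate_dataset(SimConfig(n=200, seed=12, noiseless=True))


@pytest.fixture(scope="session")
def realistic_train():
    return generate_dataset(SimConfig(n=147, seed=21))


@pytest.fixture(scope="session")
def realistic_test():
    return generate_dataset(SimConfig(n=60, seed=22))
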