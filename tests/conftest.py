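"""Shared fixtures: small graphs and benchmark networks generated at test
time (no stored data files)."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from concord.benchmark import BenchmarkParams, generate_benchmark
from concord.io import CommunityCover


@pytest.fixture(scope="session")
def triangle() -> nx.Graph:
    return nx.Graph([(0, 1), (1, 2), (2, 0)])


@pytest.fixture(scope="session")
def two_cliques() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge (0-5)."""
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    return g


@pytest.fixture(scope="session")
def two_clique_cover() -> CommunityCover:
    return CommunityCover([set(range(5)), set(range(5, 10))])


@pytest.fixture(scope="session")
def small_benchmark() -> tuple[nx.Graph, CommunityCover]:
    """One small benchmark network with planted overlapping communities."""
    return generate_benchmark(
        BenchmarkParams(N=300, C_min=10, C_max=50, mu=0.1, On=0.1, Om=2, seed=42)
    )


@pytest.fixture(scope="session")
def medium_benchmark() -> tuple[nx.Graph, CommunityCover]:
    """A benchmark network big enough for the active pipeline."""
    return generate_benchmark(
        BenchmarkParams(N=1000, C_min=10, C_max=50, mu=0.1, On=0.1, Om=2, seed=7)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
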