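import random

import pytest

from spchub import (
    ModelConfig,
    RoadNetwork,
    generate_line_region,
    run_ssm,
)


@pytest.fixture(scope="session")
def line_dataset():
    return generate_line_region()


@pytest.fixture(scope="session")
def line_results(line_dataset):
    return run_ssm(line_dataset, ModelConfig())


@pytest.fixture
def default_config():
    return ModelConfig()


def random_network(rng: random.Random, max_nodes: int = 12) -> RoadNetwork:
    """Small random weighted graph (possibly disconnected) for oracle tests."""
    n = rng.randint(2, max_nodes)
    ids = [f"v{i:02d}" for i in range(n)]
    nodes = {i: (rng.uniform(0, 1e5), rng.uniform(0, 1e5)) for i in ids}
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                edges.append((ids[i], ids[j], rng.uniform(1.0, 120.0)))
    return RoadNetwork(nodes=nodes, edges=edges)


def floyd_warshall_oracle(network: RoadNetwork):
    """Independent all-pairs shortest-path oracle (classic triple loop)."""
    inf = float("inf")
    ids = sorted(network.nodes)
    dist = {a: {b: (0.0 if a == b else inf) for b in ids} for a in ids}
    for a, b, m in network.edges:
        if m < dist[a][b]:
            dist[a][b] = dist[b][a] = m
    for k in ids:
        for i in ids:
            dik = dist[i][k]
            if dik == inf:
                continue
            for j in ids:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist
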