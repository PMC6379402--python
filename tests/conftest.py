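"""Shared fixtures and independent oracles."""

import itertools

import numpy as np
import pytest

from icell.net_io import GeneNetwork


def make_random_network(n: int, p: float, seed: int, prefix: str = "g") -> GeneNetwork:
    """Erdos–Renyi G(n, p) test network (independent of the package's
    generators: direct Bernoulli draws per pair)."""
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((nodes[i], nodes[j]))
    return GeneNetwork.from_edges(edges, nodes=nodes)


def brute_force_orbits(net: GeneNetwork) -> np.ndarray:
    """Oracle: classify every connected induced 2-4-node subgraph by its
    internal degree sequence and tally orbit memberships directly."""
    nodes = net.nodes
    n = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    adj = [set() for _ in range(n)]
    for u, v in net.edges:
        adj[pos[u]].add(pos[v])
        adj[pos[v]].add(pos[u])
    orb = np.zeros((n, 15), dtype=int)
    for u, v in itertools.combinations(range(n), 2):
        if v in adj[u]:
            orb[u, 0] += 1
            orb[v, 0] += 1
    for trip in itertools.combinations(range(n), 3):
        d = [sum(1 for o in trip if o != x and o in adj[x]) for x in trip]
        e = sum(d) // 2
        if e == 2 and min(d) >= 1:  # path
            for x, dx in zip(trip, d):
                orb[x, 1 if dx == 1 else 2] += 1
        elif e == 3:  # triangle
            for x in trip:
                orb[x, 3] += 1
    for quad in itertools.combinations(range(n), 4):
        d = [sum(1 for o in quad if o != x and o in adj[x]) for x in quad]
        e = sum(d) // 2
        if min(d) == 0:
            continue  # disconnected (isolated member)
        sd = sorted(d)
        if e == 3 and sd == [1, 1, 2, 2]:  # 4-path
            for x, dx in zip(quad, d):
                orb[x, 4 if dx == 1 else 5] += 1
        elif e == 3 and sd == [1, 1, 1, 3]:  # claw
            for x, dx in zip(quad, d):
                orb[x, 6 if dx == 1 else 7] += 1
        elif e == 4 and sd == [2, 2, 2, 2]:  # 4-cycle
            for x in quad:
                orb[x, 8] += 1
        elif e == 4 and sd == [1, 2, 2, 3]:  # paw
            for x, dx in zip(quad, d):
                orb[x, {1: 9, 2: 10, 3: 11}[dx]] += 1
        elif e == 5:  # diamond
            for x, dx in zip(quad, d):
                orb[x, 12 if dx == 2 else 13] += 1
        elif e == 6:  # clique
            for x in quad:
                orb[x, 14] += 1
    return orb


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> GeneNetwork:
    return GeneNetwork.from_edges([("a", "b"), ("b", "c")])
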