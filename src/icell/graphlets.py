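"""Graphlet orbit counting and graphlet-based distances.

Graphlets are small connected induced subgraphs; within a graphlet,
automorphism orbits distinguish topologically different node positions.
For the nine 2–4-node graphlets there are 15 orbits (0–14): orbit 0 is the
plain degree, orbits 1–2 the end/middle of a 3-path, orbit 3 the triangle,
orbits 4–14 the positions in the six 4-node graphlets (path, claw, cycle,
paw, diamond, clique).  Four of the 15 (3, 12, 13, 14) are linearly
redundant given the others, leaving the 11 non-redundant orbits
{0,1,2,4,5,6,7,8,9,10,11} used throughout.

Per-node counts are exact induced counts obtained by neighbourhood
enumeration with combinatorial corrections, O(n * d^3) for maximum degree
d; no sampling.

Distances:

* GDVD — a weighted per-orbit log distance between two nodes' graphlet
  degree vectors, bounded in [0, 1); 0 iff the vectors are identical.
* GCM / GCD-11 — a network's graphlet correlation matrix is the 11 x 11
  Spearman correlation matrix of its orbit-count columns; GCD-11 between
  two networks is the Euclidean distance between the upper triangles of
  their GCMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .net_io import GeneNetwork

#: Orbits kept after removing the linearly redundant ones (3, 12, 13, 14).
NONREDUNDANT_ORBITS: tuple[int, ...] = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)

N_ORBITS_FULL = 15
N_ORBITS = len(NONREDUNDANT_ORBITS)

#: Number of orbits that affect orbit i (the orbit itself included), for
#: orbits 0-14 of the 2-4-node graphlets.  Orbit 0 depends only on itself;
#: e.g. the middle of a 3-path (orbit 2) is also constrained by the degree,
#: giving a dependency count of 2.  These counts feed the orbit weights
#: w_i = 1 - log(o_i)/log(73), with 73 the total orbit count up to 5-node
#: graphlets for which the weighting scheme was originally defined.
ORBIT_DEPENDENCY_COUNTS: tuple[int, ...] = (1, 2, 2, 2, 3, 4, 3, 3, 4, 3, 4, 4, 4, 4, 3)


@dataclass(frozen=True)
class OrbitWeights:
    """Per-orbit weights for the 11 non-redundant orbits.

    ``weights[j]`` corresponds to ``NONREDUNDANT_ORBITS[j]``; w_0 = 1 and
    weights do not increase with the dependency count.
    """

    weights: tuple[float, ...] = field(
        default_factory=lambda: tuple(
            1.0 - math.log(ORBIT_DEPENDENCY_COUNTS[i]) / math.log(73.0)
            for i in NONREDUNDANT_ORBITS
        )
    )

    def __post_init__(self) -> None:
        if len(self.weights) != N_ORBITS:
            raise ValueError(f"need {N_ORBITS} weights")
        if any(not (0.0 < w <= 1.0) for w in self.weights):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def total(self) -> float:
        return float(sum(self.weights))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


DEFAULT_WEIGHTS = OrbitWeights()


@dataclass
class GDVTable:
    """Per-node graphlet degree vectors.

    ``counts_full`` holds all 15 orbit counts (columns = orbits 0-14) in
    the node order of the source network; ``counts`` restricts to the 11
    non-redundant orbits.
    """

    nodes: list[str]
    counts_full: np.ndarray

    def __post_init__(self) -> None:
        if self.counts_full.shape != (len(self.nodes), N_ORBITS_FULL):
            raise ValueError("counts_full shape mismatch")

    @property
    def counts(self) -> np.ndarray:
        return self.counts_full[:, list(NONREDUNDANT_ORBITS)]

    def gdv(self, node: str) -> np.ndarray:
        """The 11-dimensional non-redundant GDV of one node."""
        return self.counts[self.nodes.index(node)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {node: self.counts[i] for i, node in enumerate(self.nodes)}


def count_orbits(net: GeneNetwork) -> GDVTable:
    """Exact induced 2-4-node graphlet orbit counts for every node.

    Isolated nodes get all-zero vectors.  The counting is per-node
    enumeration over neighbour pairs/triples with combinatorial
    corrections; every 4-node subgraph class is enumerated through a
    canonical anchor (middle edge of a path, hub edge of a diamond,
    diagonal of a cycle, ...) so each induced subgraph is tallied once.
    """
    nodes = net.nodes
    n = len(nodes)
    orb = np.zeros((n, N_ORBITS_FULL), dtype=np.int64)
    if n == 0:
        return GDVTable(nodes=list(nodes), counts_full=orb)

    pos = {g: i for i, g in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, v in net.edges:
        iu, iv = pos[u], pos[v]
        adj[iu].add(iv)
        adj[iv].add(iu)
    deg = [len(a) for a in adj]
    edges = [(pos[u], pos[v]) for u, v in net.edges]

    # --- 2- and 3-node orbits -------------------------------------------
    tri = [0] * n  # triangles per node
    common: dict[tuple[int, int], set[int]] = {}
    for u, v in edges:
        c = adj[u] & adj[v]
        common[(u, v)] = c
        tri[u] += len(c)
        tri[v] += len(c)
    tri = [t // 2 for t in tri]
    for v in range(n):
        d = deg[v]
        orb[v, 0] = d
        orb[v, 2] = d * (d - 1) // 2 - tri[v]
        orb[v, 1] = sum(deg[u] - 1 for u in adj[v]) - 2 * tri[v]
        orb[v, 3] = tri[v]

    # --- K4 (orbit 14) and diamond (orbits 12, 13) ----------------------
    # Anchor: for K4, every one of the 6 edges paired with the opposite
    # adjacent pair -> each K4 produces 6 events, each node appears in all
    # 6, so divide by 6.  For the diamond, the hub edge (between the two
    # degree-3 nodes) is unique, so each diamond is tallied exactly once.
    k4_events = np.zeros(n, dtype=np.int64)
    for u, v in edges:
        cc = sorted(common[(u, v)])
        for a_idx in range(len(cc)):
            w = cc[a_idx]
            nbrs_w = adj[w]
            for b_idx in range(a_idx + 1, len(cc)):
                x = cc[b_idx]
                if x in nbrs_w:
                    k4_events[u] += 1
                    k4_events[v] += 1
                    k4_events[w] += 1
                    k4_events[x] += 1
                else:
                    orb[u, 13] += 1
                    orb[v, 13] += 1
                    orb[w, 12] += 1
                    orb[x, 12] += 1
    orb[:, 14] = k4_events // 6

    # --- C4 (orbit 8): anchor = a diagonal (non-adjacent pair with >=2
    # common neighbours); each node of a C4 sits on exactly one diagonal.
    dist2: set[tuple[int, int]] = set()
    for w in range(n):
        nb = sorted(adj[w])
        for i_ in range(len(nb)):
            for j_ in range(i_ + 1, len(nb)):
                u, v = nb[i_], nb[j_]
                if v not in adj[u]:
                    dist2.add((u, v))
    for u, v in dist2:
        s = adj[u] & adj[v]
        if len(s) < 2:
            continue
        e_in_s = sum(len(adj[w] & s) for w in s) // 2
        n_c4 = len(s) * (len(s) - 1) // 2 - e_in_s
        orb[u, 8] += n_c4
        orb[v, 8] += n_c4

    # --- paw / tailed triangle (orbits 9, 10, 11): anchor = the triangle.
    for u, v in edges:
        hi = max(u, v)
        for w in common[(u, v)]:
            if w < hi:
                continue  # each triangle tallied once: (u,v) = two lowest ids
            triangle = ((u, v, w), (v, u, w), (w, u, v))
            for a, b, c in triangle:
                pend = adj[a] - adj[b] - adj[c] - {b, c}
                orb[a, 11] += len(pend)
                orb[b, 10] += len(pend)
                orb[c, 10] += len(pend)
                for p in pend:
                    orb[p, 9] += 1

    # --- claw (orbits 6, 7) and path (orbits 4, 5) ----------------------
    for u in range(n):
        if deg[u] < 3:
            continue
        s = adj[u]
        indep_pair_sum = 0
        for x in s:
            t_x = s - adj[x]
            t_x.discard(x)
            e_tx = sum(len(adj[y] & t_x) for y in t_x) // 2
            pairs = len(t_x) * (len(t_x) - 1) // 2 - e_tx
            orb[x, 6] += pairs
            indep_pair_sum += pairs
        orb[u, 7] += indep_pair_sum // 3  # each claw seen once per leaf

    for u, v in edges:
        # induced 4-path a-u-v-b anchored at its unique middle edge
        a_side = adj[u] - adj[v] - {v}
        b_side = adj[v] - adj[u] - {u}
        cross = sum(len(adj[a] & b_side) for a in a_side)
        n_p4 = len(a_side) * len(b_side) - cross
        orb[u, 5] += n_p4
        orb[v, 5] += n_p4
        for a in a_side:
            orb[a, 4] += len(b_side) - len(adj[a] & b_side)
        for b in b_side:
            orb[b, 4] += len(a_side) - len(adj[b] & a_side)

    return GDVTable(nodes=list(nodes), counts_full=orb)


def gdv_distance(
    h: Sequence[float] | np.ndarray,
    c: Sequence[float] | np.ndarray,
    weights: OrbitWeights = DEFAULT_WEIGHTS,
) -> float:
    """Weighted log-scale distance between two graphlet degree vectors.

    Per orbit i, ``D_i = w_i * |log(h_i+1) - log(c_i+1)| / log(max(h_i,c_i)+2)``
    and the distance is ``sum(D_i) / sum(w_i)``; natural logs (the ratio is
    base-invariant).  Always in [0, 1); 0 iff the vectors are equal.
    """
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if h.shape != (N_ORBITS,) or c.shape != (N_ORBITS,):
        raise ValueError(f"GDVs must be {N_ORBITS}-vectors")
    if np.any(h < 0) or np.any(c < 0):
        raise ValueError("GDV counts must be non-negative")
    w = weights.as_array()
    num = np.abs(np.log(h + 1.0) - np.log(c + 1.0))
    den = np.log(np.maximum(h, c) + 2.0)
    return float(np.sum(w * num / den) / np.sum(w))


def gdv_distance_many(
    h: np.ndarray, c: np.ndarray, weights: OrbitWeights = DEFAULT_WEIGHTS
) -> np.ndarray:
    """Row-wise :func:`gdv_distance` for two (r, 11) count arrays."""
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    if h.shape != c.shape or h.ndim != 2 or h.shape[1] != N_ORBITS:
        raise ValueError(f"expected matching (r, {N_ORBITS}) arrays")
    if np.any(h < 0) or np.any(c < 0):
        raise ValueError("GDV counts must be non-negative")
    w = weights.as_array()
    num = np.abs(np.log(h + 1.0) - np.log(c + 1.0))
    den = np.log(np.maximum(h, c) + 2.0)
    return np.sum(w * num / den, axis=1) / np.sum(w)


@dataclass
class GCMatrix:
    """11 x 11 Spearman correlation matrix of orbit-count columns."""

    matrix: np.ndarray
    dummy_row_added: bool = True

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_ORBITS, N_ORBITS):
            raise ValueError("GCM must be 11 x 11")
        if not np.allclose(m, m.T):
            raise ValueError("GCM must be symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(N_ORBITS, k=1)
        return self.matrix[iu]


def graphlet_correlation_matrix(
    net: GeneNetwork, gdv: GDVTable | None = None
) -> GCMatrix:
    """Spearman correlations between non-redundant orbit counts over nodes.

    One artificial all-ones GDV row is appended before correlating so that
    orbit columns that are constant over the real nodes (typically all
    zero) still have a defined rank correlation.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    counts = (gdv if gdv is not None else count_orbits(net)).counts
    data = np.vstack([counts, np.ones((1, N_ORBITS))])
    rho = stats.spearmanr(data, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    rho[~np.isfinite(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return GCMatrix(matrix=rho, dummy_row_added=True)


def gcd11(net1: GeneNetwork, net2: GeneNetwork) -> float:
    """GCD-11 distance between two networks.

    Euclidean norm over the 55 strictly-upper-triangle entries of the
    difference of their graphlet correlation matrices.  Symmetric in its
    arguments; 0 for isomorphic inputs.
    """
    g1 = graphlet_correlation_matrix(net1)
    g2 = graphlet_correlation_matrix(net2)
    return gcd11_from_gcms(g1, g2)


def gcd11_from_gcms(g1: GCMatrix, g2: GCMatrix) -> float:
    return float(np.linalg.norm(g1.upper_triangle() - g2.upper_triangle()))
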