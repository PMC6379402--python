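"""Synthetic fixtures with known ground truth.

Three generators cover the downstream stages:

* :func:`simulate_multiplex` — planted co-clustered multiplex networks (a
  multilayer stochastic block model with one shared partition), the
  recovery target for the tri-factorization;
* :func:`simulate_condition_pair` — a control/case pair in which a chosen
  set of genes has part of its wiring randomly re-routed in the case
  condition, the recovery target for graphlet-based rewiring scores;
* :func:`simulate_annotations` — annotation terms aligned with the planted
  clusters at a chosen coverage and noise level, the positive control for
  the enrichment statistics.

Every generator is deterministic given its seed; seeds are echoed in the
returned parameter records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .net_io import ExpressionProfile, GeneNetwork, MultiplexNetworks, _norm_edge


@dataclass
class PlantedMultiplex:
    """A multiplex with a known gene partition."""

    multiplex: MultiplexNetworks
    truth_clusters: dict[str, int]
    params: dict = field(default_factory=dict)


@dataclass
class ConditionPair:
    """Control and case multiplexes with planted rewired genes."""

    control: MultiplexNetworks
    case: MultiplexNetworks
    rewired_genes: set[str]
    expression: ExpressionProfile
    params: dict = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def simulate_multiplex(
    n: int,
    k: int,
    m: int,
    p_in: float | Sequence[float],
    p_out: float | Sequence[float],
    seed: int | None = None,
) -> PlantedMultiplex:
    """Planted-partition multiplex: within-cluster pairs get an edge with
    probability ``p_in`` per layer, between-cluster pairs with ``p_out``.

    ``p_in``/``p_out`` may be scalars (shared by all layers) or length-m
    sequences.  Cluster sizes are as equal as possible (n divisible by k
    gives exactly equal sizes).  ``p_in < p_out`` in any layer is rejected
    as degenerate planted structure.
    """
    p_in_l = [float(p_in)] * m if np.isscalar(p_in) else [float(x) for x in p_in]
    p_out_l = [float(p_out)] * m if np.isscalar(p_out) else [float(x) for x in p_out]
    if len(p_in_l) != m or len(p_out_l) != m:
        raise ValueError("per-layer probabilities must have length m")
    for pi, po in zip(p_in_l, p_out_l):
        if not (0.0 <= po <= pi <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1 in every layer")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n)
    labels = np.array([i % k for i in range(n)], dtype=int)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    matrices: list[np.ndarray] = []
    for pi, po in zip(p_in_l, p_out_l):
        probs = np.where(same[iu], pi, po)
        draws = rng.random(probs.shape) < probs
        a = np.zeros((n, n))
        a[iu] = draws.astype(float)
        a = a + a.T
        matrices.append(a)
    multiplex = MultiplexNetworks(
        gene_index=genes,
        matrices=matrices,
        layer_labels=[f"layer{i}" for i in range(m)],
    )
    truth = {g: int(lab) + 1 for g, lab in zip(genes, labels)}
    return PlantedMultiplex(
        multiplex=multiplex,
        truth_clusters=truth,
        params={"n": n, "k": k, "m": m, "p_in": p_in_l, "p_out": p_out_l, "seed": seed},
    )


def simulate_condition_pair(
    base: PlantedMultiplex,
    n_rewired: int,
    rewiring_strength: float,
    seed: int | None = None,
    silenced_fraction: float = 0.0,
) -> ConditionPair:
    """Derive a case condition by rewiring selected genes.

    The case starts as a copy of the control.  For each of ``n_rewired``
    uniformly chosen genes, per layer, a fraction ``rewiring_strength`` of
    its incident edges is removed and replaced by the same number of edges
    to uniformly chosen non-neighbors (degree approximately preserved).
    Unless ``silenced_fraction`` > 0, every gene is marked expressed in
    both conditions; silenced genes are drawn from the non-rewired pool so
    rewired genes are always expressed in both conditions.
    """
    if not (0.0 <= rewiring_strength <= 1.0):
        raise ValueError("rewiring_strength must be in [0, 1]")
    genes = base.multiplex.gene_index
    n = len(genes)
    if n_rewired > n:
        raise ValueError("n_rewired cannot exceed the number of genes")
    if not (0.0 <= silenced_fraction <= 1.0):
        raise ValueError("silenced_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rewired_idx = sorted(rng.choice(n, size=n_rewired, replace=False).tolist())
    case_matrices = [np.array(a, copy=True) for a in base.multiplex.matrices]
    for a in case_matrices:
        for gi in rewired_idx:
            neighbors = np.nonzero(a[gi])[0]
            n_move = int(round(rewiring_strength * neighbors.size))
            if n_move == 0:
                continue
            removed = rng.choice(neighbors, size=n_move, replace=False)
            for r in removed:
                a[gi, r] = 0.0
                a[r, gi] = 0.0
            non_neighbors = np.array(
                [j for j in range(n) if j != gi and a[gi, j] == 0.0]
            )
            n_add = min(n_move, non_neighbors.size)
            added = rng.choice(non_neighbors, size=n_add, replace=False)
            for t in added:
                a[gi, t] = 1.0
                a[t, gi] = 1.0
    case = MultiplexNetworks(
        gene_index=list(genes),
        matrices=case_matrices,
        layer_labels=list(base.multiplex.layer_labels),
    )
    rewired_genes = {genes[i] for i in rewired_idx}
    expressed_control = set(genes)
    expressed_case = set(genes)
    if silenced_fraction > 0.0:
        pool = sorted(set(range(n)) - set(rewired_idx))
        n_sil = int(round(silenced_fraction * len(pool)))
        if n_sil:
            sil = rng.choice(pool, size=n_sil, replace=False)
            half = n_sil // 2
            expressed_control -= {genes[i] for i in sil[:half]}
            expressed_case -= {genes[i] for i in sil[half:]}
    expression = ExpressionProfile(
        calls={"control": expressed_control, "case": expressed_case}
    )
    return ConditionPair(
        control=base.multiplex,
        case=case,
        rewired_genes=rewired_genes,
        expression=expression,
        params={
            "n_rewired": n_rewired,
            "rewiring_strength": rewiring_strength,
            "seed": seed,
            "silenced_fraction": silenced_fraction,
            "base_params": dict(base.params),
        },
    )


def simulate_annotations(
    truth_clusters: dict[str, int],
    n_terms_per_cluster: int = 2,
    coverage: float = 0.8,
    noise: float = 0.02,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """Cluster-aligned annotation terms, GMT-writable.

    Each term draws a ``coverage`` fraction of one cluster's genes plus a
    ``noise`` fraction of the genes outside that cluster.
    """
    if not (0.0 <= coverage <= 1.0) or not (0.0 <= noise <= 1.0):
        raise ValueError("coverage and noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    clusters: dict[int, list[str]] = {}
    for g, c in truth_clusters.items():
        clusters.setdefault(c, []).append(g)
    for members in clusters.values():
        members.sort()
    all_genes = sorted(truth_clusters)
    terms: dict[str, set[str]] = {}
    for c in sorted(clusters):
        members = clusters[c]
        outside = [g for g in all_genes if truth_clusters[g] != c]
        for t in range(n_terms_per_cluster):
            n_cov = int(round(coverage * len(members)))
            n_noise = int(round(noise * len(outside)))
            term_genes: set[str] = set()
            if n_cov:
                term_genes |= set(rng.choice(members, size=n_cov, replace=False))
            if n_noise:
                term_genes |= set(rng.choice(outside, size=n_noise, replace=False))
            terms[f"term_c{c}_{t}"] = term_genes
    return terms


def networks_from_multiplex(multiplex: MultiplexNetworks) -> list[GeneNetwork]:
    """All layers of a multiplex as :class:`GeneNetwork` objects."""
    return [multiplex.layer_network(i) for i in range(multiplex.n_layers)]


def random_gnp_network(
    n: int, p: float, seed: int | None = None, prefix: str = "g"
) -> GeneNetwork:
    """Erdos–Renyi G(n, p) convenience fixture over synthetic gene names."""
    rng = np.random.default_rng(seed)
    genes = [f"{prefix}{i}" for i in range(n)]
    edges: set[tuple[str, str]] = set()
    iu, ju = np.triu_indices(n, k=1)
    draws = rng.random(iu.size) < p
    for a, b in zip(iu[draws].tolist(), ju[draws].tolist()):
        edges.add(_norm_edge(genes[a], genes[b]))
    return GeneNetwork(nodes=genes, edges=edges, layer_label="er")
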