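"""Random-graph null models and GCD-11 model fitting.

Seven generative models commonly compared against molecular networks:

* **ER** — uniformly random edges at an exact target edge count;
* **ER-DD** — random graph constrained to a given degree sequence (stub
  matching with rejection of self-loops/multi-edges);
* **GEO** — points uniform in the unit cube (dimension 3 by default),
  edges between pairs closer than a radius calibrated to the target
  density;
* **GEO-GD** — node positions grown by duplication (child placed within
  2r of its parent) with a final GEO edge pass;
* **SF** — Barabasi–Albert preferential attachment;
* **SF-GD** — duplication–divergence: a duplicated node inherits its
  parent's neighbours, attaches to the parent with probability p, and
  loses each shared neighbour with probability q (q calibrated to the
  target density);
* **STICKY** — each pair connected independently with probability
  theta_i * theta_j, stickiness indexes proportional to an input degree
  sequence.

Fit between a data network and a model is judged by comparing the
distribution of GCD-11 distances from the data network to model replicas
against the distribution among model replicas, with a two-sided
Mann–Whitney U test: the model is rejected as a fit when p <= 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .graphlets import GCMatrix, gcd11_from_gcms, graphlet_correlation_matrix
from .net_io import GeneNetwork, _norm_edge

MODEL_NAMES = ("ER", "ER-DD", "GEO", "GEO-GD", "SF", "SF-GD", "STICKY")


@dataclass
class ModelParams:
    """Parameters of one model draw.

    ``density`` is the target edge density; ``degree_sequence`` feeds
    ER-DD and STICKY; ``dim`` is the embedding dimension of the GEO
    family; ``p`` the SF-GD parent-attachment probability (q is
    calibrated to the density).
    """

    model: str
    n: int
    density: float | None = None
    degree_sequence: Sequence[int] | None = None
    dim: int = 3
    p: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.density is not None and not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.degree_sequence is not None:
            if sum(self.degree_sequence) % 2 != 0:
                raise ValueError("degree sequence must sum to an even number")


@dataclass
class ModelFit:
    model: str
    real_to_model: np.ndarray
    model_to_model: np.ndarray
    mwu_p: float
    mean_distance: float
    sd_distance: float

    @property
    def rejected(self) -> bool:
        return self.mwu_p <= 0.05


@dataclass
class ModelFitResult:
    real_label: str
    reps: int
    fits: dict[str, ModelFit] = field(default_factory=dict)


def _nodes(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"n{str(i).zfill(width)}" for i in range(n)]


def _net(n: int, edge_idx: set[tuple[int, int]], label: str) -> GeneNetwork:
    names = _nodes(n)
    edges = {_norm_edge(names[a], names[b]) for a, b in edge_idx}
    return GeneNetwork(nodes=names, edges=edges, layer_label=label)


def _target_edges(n: int, density: float) -> int:
    return int(round(density * n * (n - 1) / 2))


def _er(n: int, density: float, rng: np.random.Generator) -> set[tuple[int, int]]:
    m = _target_edges(n, density)
    total = n * (n - 1) // 2
    chosen = rng.choice(total, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    return {(int(iu[c]), int(ju[c])) for c in chosen}


def _er_dd(
    degree_sequence: Sequence[int], rng: np.random.Generator, max_restarts: int = 100
) -> tuple[set[tuple[int, int]], int]:
    """Stub matching with collision re-shuffling and edge-swap repair.

    Returns (edges, residual unmatched stubs): stubs colliding into
    self-loops or multi-edges are re-paired; stubborn collisions are
    repaired by rewiring an existing edge; whatever remains is dropped.
    """
    n = len(degree_sequence)
    best: set[tuple[int, int]] | None = None
    best_residual: int | None = None
    for _ in range(max_restarts):
        edges: set[tuple[int, int]] = set()
        pending = np.repeat(np.arange(n), degree_sequence).tolist()
        for _round in range(50):
            rng.shuffle(pending)
            retry: list[int] = []
            for a, b in zip(pending[0::2], pending[1::2]):
                e = (a, b) if a < b else (b, a)
                if a == b or e in edges:
                    retry.extend((a, b))
                else:
                    edges.add(e)
            if len(pending) % 2:
                retry.append(pending[-1])
            if len(retry) >= len(pending):
                break  # no progress
            pending = retry
            if len(pending) < 2:
                break
        # swap repair: satisfy a stuck stub pair (a, b) by rewiring an
        # existing edge (c, d) into (a, c) and (b, d)
        still: list[int] = []
        pending_iter = iter(pending)
        for a, b in zip(pending_iter, pending_iter):
            repaired = False
            edge_list = list(edges)
            if not edge_list:
                still.extend((a, b))
                continue
            for _try in range(50):
                c, d = edge_list[int(rng.integers(len(edge_list)))]
                if rng.random() < 0.5:
                    c, d = d, c
                e1 = (a, c) if a < c else (c, a)
                e2 = (b, d) if b < d else (d, b)
                if a != c and b != d and e1 not in edges and e2 not in edges:
                    edges.discard((c, d) if c < d else (d, c))
                    edges.add(e1)
                    edges.add(e2)
                    repaired = True
                    break
            if not repaired:
                still.extend((a, b))
        if len(pending) % 2:
            still.append(0)  # odd leftover stub counts as residual
        leftover = len(still)
        if best_residual is None or leftover < best_residual:
            best, best_residual = edges, leftover
        if leftover == 0:
            break
    assert best is not None and best_residual is not None
    return best, best_residual


def _geo_edges_at_radius(points: np.ndarray, r: float) -> set[tuple[int, int]]:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    iu = np.triu_indices(points.shape[0], k=1)
    keep = d[iu] <= r
    return {(int(a), int(b)) for a, b in zip(iu[0][keep], iu[1][keep])}


def _radius_for_density(points: np.ndarray, density: float) -> float:
    """Radius hitting the target edge count exactly: the m-th smallest
    pairwise distance."""
    n = points.shape[0]
    m = _target_edges(n, density)
    iu = np.triu_indices(n, k=1)
    dists = np.sort(np.linalg.norm(points[iu[0]] - points[iu[1]], axis=1))
    if m == 0:
        return 0.0
    return float(dists[m - 1])


def _geo(n: int, density: float, dim: int, rng: np.random.Generator):
    points = rng.uniform(size=(n, dim))
    r = _radius_for_density(points, density)
    return _geo_edges_at_radius(points, r), points, r


def _geo_gd(n: int, density: float, dim: int, rng: np.random.Generator):
    # provisional radius from the uniform-ball expected-density formula,
    # used only for the 2r duplication placement
    unit_ball = math.pi ** (dim / 2) / math.gamma(dim / 2 + 1)
    r0 = min(0.5, (density / unit_ball) ** (1.0 / dim))
    points = [rng.uniform(size=dim), rng.uniform(size=dim)]
    while len(points) < n:
        parent = points[int(rng.integers(len(points)))]
        # uniform point in the ball of radius 2*r0 around the parent
        direction = rng.normal(size=dim)
        direction /= np.linalg.norm(direction)
        radius = 2.0 * r0 * rng.uniform() ** (1.0 / dim)
        child = np.clip(parent + radius * direction, 0.0, 1.0)
        assert np.linalg.norm(child - parent) <= 2.0 * r0 + 1e-9
        points.append(child)
    pts = np.asarray(points)
    r = _radius_for_density(pts, density)
    return _geo_edges_at_radius(pts, r), pts, r


def _sf(n: int, density: float, rng: np.random.Generator) -> set[tuple[int, int]]:
    m_attach = max(1, int(round(density * (n - 1) / 2.0)))
    if m_attach >= n:
        raise ValueError("density too high for preferential attachment")
    # preferential attachment from a single-edge seed
    edges: set[tuple[int, int]] = {(0, 1)}
    targets_pool = [0, 1]  # node repeated once per degree
    for v in range(2, n):
        chosen: set[int] = set()
        attempts = 0
        k = min(m_attach, v)
        while len(chosen) < k and attempts < 100 * k:
            t = targets_pool[int(rng.integers(len(targets_pool)))]
            chosen.add(t)
            attempts += 1
        for t in chosen:
            edges.add((t, v) if t < v else (v, t))
            targets_pool.extend((t, v))
    return edges


def _sf_gd_once(
    n: int, p: float, q: float, rng: np.random.Generator
) -> set[tuple[int, int]]:
    adj: list[set[int]] = [{1}, {0}]
    for v in range(2, n):
        parent = int(rng.integers(len(adj)))
        child = len(adj)
        child_nbrs = set(adj[parent])  # inherits all parent neighbours
        adj.append(set())
        for u in child_nbrs:
            adj[child].add(u)
            adj[u].add(child)
        if rng.uniform() < p:
            adj[child].add(parent)
            adj[parent].add(child)
        # divergence: drop the child's link to each shared neighbour w.p. q
        for u in sorted(child_nbrs & adj[parent]):
            if rng.uniform() < q:
                adj[child].discard(u)
                adj[u].discard(child)
    edges: set[tuple[int, int]] = set()
    for a, nbrs in enumerate(adj):
        for b in nbrs:
            if a < b:
                edges.add((a, b))
    return edges


def _sf_gd(
    n: int, density: float, p: float, rng: np.random.Generator,
    max_bisect: int = 50, draws_per_step: int = 3, tol: float = 0.05,
) -> set[tuple[int, int]]:
    """Calibrate the divergence probability q to the target density by
    bisection on repeated draws, then emit one draw at the calibrated q."""
    target = density

    def mean_density(q: float) -> float:
        dens = []
        for _ in range(draws_per_step):
            e = _sf_gd_once(n, p, q, rng)
            dens.append(2.0 * len(e) / (n * (n - 1)))
        return float(np.mean(dens))

    lo, hi = 0.0, 1.0
    q = 0.5
    for _ in range(max_bisect):
        q = (lo + hi) / 2.0
        d = mean_density(q)
        if abs(d - target) <= tol * target:
            break
        if d > target:
            lo = q  # more divergence -> fewer edges
        else:
            hi = q
    else:
        raise RuntimeError(
            f"SF-GD density calibration did not converge after {max_bisect} steps"
        )
    # emit the candidate draw closest to the target density
    candidates = [_sf_gd_once(n, p, q, rng) for _ in range(5)]
    return min(
        candidates, key=lambda e: abs(2.0 * len(e) / (n * (n - 1)) - target)
    )


def _sticky(
    degree_sequence: Sequence[int], rng: np.random.Generator
) -> set[tuple[int, int]]:
    deg = np.asarray(degree_sequence, dtype=float)
    total = deg.sum()
    if total <= 0:
        return set()
    theta = deg / math.sqrt(total)
    n = len(deg)
    iu = np.triu_indices(n, k=1)
    probs = np.minimum(1.0, theta[iu[0]] * theta[iu[1]])
    keep = rng.random(probs.shape) < probs
    return {(int(a), int(b)) for a, b in zip(iu[0][keep], iu[1][keep])}


def generate_model(params: ModelParams) -> GeneNetwork:
    """Draw one simple undirected network from the requested model."""
    rng = np.random.default_rng(params.seed)
    model, n = params.model, params.n
    if model in ("ER", "GEO", "GEO-GD", "SF", "SF-GD") and params.density is None:
        raise ValueError(f"{model} requires a target density")
    if model in ("ER-DD", "STICKY") and params.degree_sequence is None:
        raise ValueError(f"{model} requires a degree sequence")
    if model == "ER":
        edges = _er(n, params.density, rng)
    elif model == "ER-DD":
        if len(params.degree_sequence) != n:
            raise ValueError("degree sequence length must equal n")
        if max(params.degree_sequence) >= n:
            raise ValueError("unsatisfiable degree sequence (degree >= n)")
        edges, _residual = _er_dd(params.degree_sequence, rng)
    elif model == "GEO":
        edges, _, _ = _geo(n, params.density, params.dim, rng)
    elif model == "GEO-GD":
        edges, _, _ = _geo_gd(n, params.density, params.dim, rng)
    elif model == "SF":
        edges = _sf(n, params.density, rng)
    elif model == "SF-GD":
        edges = _sf_gd(n, params.density, params.p, rng)
    else:  # STICKY
        if len(params.degree_sequence) != n:
            raise ValueError("degree sequence length must equal n")
        edges = _sticky(params.degree_sequence, rng)
    return _net(n, edges, label=model)


def match_params(
    real: GeneNetwork, model: str, seed: int | None = None
) -> ModelParams:
    """Model parameters matching the real network's size and density (and
    degree sequence where the model needs one)."""
    deg = [real.degree()[g] for g in real.nodes]
    return ModelParams(
        model=model,
        n=real.n_nodes,
        density=real.density(),
        degree_sequence=deg if model in ("ER-DD", "STICKY") else None,
        seed=seed,
    )


def fit_models(
    real: GeneNetwork,
    models: Sequence[str] = MODEL_NAMES,
    reps: int = 30,
    seed: int | None = None,
) -> ModelFitResult:
    """GCD-11 model-fitting experiment.

    For each model, ``reps`` replicas matching the real network's node
    count and edge density are generated; the distribution of GCD-11
    distances between the real network and the replicas is compared with
    the distribution among replicas (C(reps, 2) distances) by a two-sided
    Mann–Whitney U test (normal approximation with tie correction).
    """
    if reps < 2:
        raise ValueError("need reps >= 2")
    if real.n_edges == 0:
        raise ValueError("degenerate real network: no edges")
    master = np.random.default_rng(seed)
    real_gcm = graphlet_correlation_matrix(real)
    result = ModelFitResult(real_label=real.layer_label, reps=reps)
    for model in models:
        gcms: list[GCMatrix] = []
        for _ in range(reps):
            rep_seed = int(master.integers(2**31 - 1))
            net = generate_model(match_params(real, model, seed=rep_seed))
            gcms.append(graphlet_correlation_matrix(net))
        real_to_model = np.array([gcd11_from_gcms(real_gcm, g) for g in gcms])
        model_to_model = np.array(
            [gcd11_from_gcms(a, b) for a, b in itertools.combinations(gcms, 2)]
        )
        mwu = stats.mannwhitneyu(
            real_to_model, model_to_model, alternative="two-sided", method="asymptotic"
        )
        result.fits[model] = ModelFit(
            model=model,
            real_to_model=real_to_model,
            model_to_model=model_to_model,
            mwu_p=float(mwu.pvalue),
            mean_distance=float(real_to_model.mean()),
            sd_distance=float(real_to_model.std(ddof=1)),
        )
    return result
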