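"""Simultaneous symmetric non-negative matrix tri-factorization (MSNMTF).

All condition-specific adjacency matrices A_i are decomposed at once as
A_i ~ G S_i G^T with one shared non-negative cluster-indicator matrix G
(n genes x k clusters) and per-layer compressed matrices S_i (k x k),
minimizing sum_i ||A_i - G S_i G^T||_F^2.  The solver is a fixed-point
scheme alternating the closed-form S update

    S_i = (G^T G)^-1 (G^T A_i G) (G^T G)^-1

with a multiplicative update of G; a small ridge epsilon (~1e-10) is added
to the Gram diagonal before inversion for numerical stability.  Quality is
tracked by the relative square error

    RSE = sum_i ||A_i - G S_i G^T||_F^2 / sum_i ||A_i||_F^2 .

From a converged G:

* the integrated network keeps, in W = G G^T (diagonal removed), the
  entries that are among the top fraction of their row or column;
* hard clustering assigns each gene to argmax_i G[u][i].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .net_io import GeneNetwork, MultiplexNetworks, _norm_edge


@dataclass
class SolverConfig:
    """Solver settings.

    Parameters
    ----------
    k
        Number of clusters (columns of G).
    max_iter
        Fixed iteration budget; default 1000, past which the RSE no longer
        decreases appreciably on typical inputs.
    epsilon
        Ridge added to the Gram diagonal before inversion, and to the
        multiplicative-update denominator (so 0/0 positions leave G
        unchanged).
    init
        ``"svd"`` (deterministic), ``"acol"`` (randomized data-driven:
        each column of G_init averages a few random columns of the mean
        adjacency), or ``"random"`` (plain uniform entries).  ``"acol"``
        is the recommended non-deterministic initialization: uniform
        entries tend to collapse columns under the multiplicative
        updates, whereas averaged adjacency columns start G near distinct
        neighbourhood profiles while keeping run-to-run variability.
    seed
        RNG seed for random initialization.
    update_orientation
        ``"standard"`` places (A_i G S_i)^+ in the update numerator (the
        orientation with guaranteed descent); ``"flipped"`` swaps the
        positive/negative parts of that term.
    normalize_g
        If True (default), resolve the tri-factor scale indeterminacy
        (G -> G D, S_i -> D^-1 S_i D^-1 leaves the objective unchanged) by
        rescaling the returned G to unit-L2-norm columns, with S_i
        compensated.  This makes the per-row argmax used for hard
        clustering comparable across columns.
    early_stop
        If True, stop once |delta RSE| < 1e-9 for 10 consecutive
        iterations (off by default; the fixed budget is the reference
        behaviour).
    """

    k: int
    max_iter: int = 1000
    epsilon: float = 1e-10
    init: str = "svd"
    seed: int | None = None
    update_orientation: str = "standard"
    normalize_g: bool = True
    early_stop: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.init not in ("svd", "random", "acol"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.update_orientation not in ("standard", "flipped"):
            raise ValueError(f"unknown update_orientation {self.update_orientation!r}")


@dataclass
class InitSolution:
    """An initial G with its provenance."""

    G_init: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.G_init < 0):
            raise ValueError("G_init must be non-negative")


@dataclass
class FactorizationResult:
    G: np.ndarray
    S: list[np.ndarray]
    rse_trace: list[float]
    iterations_run: int
    config: SolverConfig

    @property
    def final_rse(self) -> float:
        return self.rse_trace[-1]


@dataclass
class ICellNetwork:
    """Thresholded integrated network derived from G G^T."""

    network: GeneNetwork
    weights: dict[tuple[str, str], float]
    threshold_fraction: float = 0.01


@dataclass
class Clustering:
    """Total hard assignment of genes to clusters 1..k."""

    assignment: dict[str, int]
    k: int

    def labels(self, gene_index: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[g] for g in gene_index], dtype=int)

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, set()).add(g)
        return out


def _pos_neg(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split into positive and negative parts: m = m_pos - m_neg, both >= 0."""
    a = np.abs(m)
    return (a + m) / 2.0, (a - m) / 2.0


def init_random(n: int, k: int, seed: int | None = None) -> InitSolution:
    """Uniform(0, 1) entries; non-deterministic runs underpin the stability
    analysis used to choose k."""
    rng = np.random.default_rng(seed)
    return InitSolution(G_init=rng.uniform(size=(n, k)), method="random", seed=seed)


def init_acol(
    multiplex: MultiplexNetworks, k: int, seed: int | None = None, p: int = 5
) -> InitSolution:
    """Randomized data-driven initialization ("random acol").

    Each column of G_init is the mean of ``p`` uniformly drawn columns of
    the average adjacency matrix.  Runs differ through the column draws,
    giving the run-to-run variability the stability analysis relies on,
    while starting G near actual neighbourhood profiles (plain uniform
    entries tend to collapse columns under the multiplicative updates).
    """
    rng = np.random.default_rng(seed)
    n = multiplex.n_genes
    if k > n:
        raise ValueError("k cannot exceed the number of genes")
    a_bar = sum(multiplex.matrices) / multiplex.n_layers
    p = min(p, n)
    cols = [
        a_bar[:, rng.choice(n, size=p, replace=False)].mean(axis=1)
        for _ in range(k)
    ]
    g = np.column_stack(cols) + 1e-6  # keep strictly positive
    return InitSolution(G_init=g, method="acol", seed=seed)


def init_svd(multiplex: MultiplexNetworks, k: int) -> InitSolution:
    """Deterministic initialization from the SVD of the average adjacency.

    Column i of G_init is sigma_i * g_i where sigma_i is the square root
    of the i-th largest singular value of the average adjacency matrix and
    g_i is whichever of the non-negative parts max(v_i, 0), -min(v_i, 0)
    of the i-th left singular vector has the larger norm (a sign-invariant
    choice).  Columns beyond the numerical rank are zero-padded with a
    warning.
    """
    if k > multiplex.n_genes:
        raise ValueError("k cannot exceed the number of genes")
    a_bar = sum(multiplex.matrices) / multiplex.n_layers
    # A-bar is symmetric: its singular vectors are its eigenvectors and the
    # singular values the |eigenvalues|.  eigh gives a deterministic basis
    # (ties broken toward the more positive eigenvalue).
    eigvals, eigvecs = np.linalg.eigh(a_bar)
    order = sorted(range(len(eigvals)), key=lambda i: (-abs(eigvals[i]), -eigvals[i]))
    s = np.abs(eigvals[order])
    u = eigvecs[:, order]
    tol = max(a_bar.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    g = np.zeros((multiplex.n_genes, k))
    padded = 0
    for i in range(k):
        if i >= s.size or s[i] <= tol:
            padded += 1
            continue
        v = u[:, i]
        v_pos = np.maximum(v, 0.0)
        v_neg = -np.minimum(v, 0.0)
        part = v_pos if np.linalg.norm(v_pos) > np.linalg.norm(v_neg) else v_neg
        g[:, i] = np.sqrt(s[i]) * part
    if padded:
        warnings.warn(
            f"average adjacency has numerical rank < k; {padded} zero-padded column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    return InitSolution(G_init=g, method="svd")


def update_s(a_i: np.ndarray, g: np.ndarray, epsilon: float = 1e-10) -> np.ndarray:
    """Closed-form optimal S_i given G, symmetrized against round-off."""
    if a_i.shape[0] != g.shape[0]:
        raise ValueError("adjacency / G shape mismatch")
    gram = g.T @ g + epsilon * np.eye(g.shape[1])
    gram_inv = np.linalg.inv(gram)
    s = gram_inv @ (g.T @ a_i @ g) @ gram_inv
    return (s + s.T) / 2.0


def update_g(
    multiplex: MultiplexNetworks,
    s_list: Sequence[np.ndarray],
    g: np.ndarray,
    epsilon: float = 1e-10,
    orientation: str = "standard",
) -> np.ndarray:
    """One multiplicative update of G; preserves non-negativity.

    Elementwise, G <- G * sqrt(num / den) where the numerator collects
    (A_i G S_i)^+ and (G (S_i G^T G S_i))^- over layers and the
    denominator the opposite parts ("standard" orientation; "flipped"
    swaps the roles of (A_i G S_i)^+/-).  The denominator is guarded by
    epsilon so 0/0 positions leave G unchanged.
    """
    num = np.zeros_like(g)
    den = np.zeros_like(g)
    gram = g.T @ g
    for a_i, s_i in zip(multiplex.matrices, s_list):
        ags = a_i @ g @ s_i
        ags_pos, ags_neg = _pos_neg(ags)
        core = s_i @ gram @ s_i
        core_pos, core_neg = _pos_neg(core)
        if orientation == "standard":
            num += ags_pos + g @ core_neg
            den += ags_neg + g @ core_pos
        else:
            num += ags_neg + g @ core_pos
            den += ags_pos + g @ core_neg
    ratio = (num + epsilon) / (den + epsilon)
    return g * np.sqrt(ratio)


def rse(
    multiplex: MultiplexNetworks, g: np.ndarray, s_list: Sequence[np.ndarray]
) -> float:
    """Relative square error of the factorization (0 = exact)."""
    denom = sum(float(np.sum(a * a)) for a in multiplex.matrices)
    if denom == 0.0:
        raise ValueError("all layers are empty: RSE undefined")
    numer = 0.0
    for a_i, s_i in zip(multiplex.matrices, s_list):
        resid = a_i - g @ s_i @ g.T
        numer += float(np.sum(resid * resid))
    return numer / denom


def fuse(
    multiplex: MultiplexNetworks,
    config: SolverConfig,
    init: InitSolution | None = None,
) -> FactorizationResult:
    """Run the fixed-point MSNMTF solver.

    Each iteration recomputes every S_i in closed form, applies one
    multiplicative update to G, and records the RSE.  Deterministic given
    the initialization (SVD init, or random init with a seed).
    """
    if config.k > multiplex.n_genes:
        raise ValueError("k cannot exceed the number of genes")
    if config.max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if init is None:
        if config.init == "svd":
            init = init_svd(multiplex, config.k)
        elif config.init == "acol":
            init = init_acol(multiplex, config.k, seed=config.seed)
        else:
            init = init_random(multiplex.n_genes, config.k, seed=config.seed)
    g = np.array(init.G_init, dtype=float, copy=True)
    if g.shape != (multiplex.n_genes, config.k):
        raise ValueError("initial G has the wrong shape")

    trace: list[float] = []
    s_list: list[np.ndarray] = []
    flat_count = 0
    iterations = 0
    for it in range(1, config.max_iter + 1):
        s_list = [update_s(a, g, config.epsilon) for a in multiplex.matrices]
        g = update_g(
            multiplex, s_list, g, epsilon=config.epsilon,
            orientation=config.update_orientation,
        )
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite values in G at iteration {it}")
        current = rse(multiplex, g, s_list)
        trace.append(current)
        iterations = it
        if config.early_stop and len(trace) >= 2:
            if abs(trace[-2] - trace[-1]) < 1e-9:
                flat_count += 1
                if flat_count >= 10:
                    break
            else:
                flat_count = 0
    if config.normalize_g:
        norms = np.linalg.norm(g, axis=0)
        g = g / np.where(norms > 0, norms, 1.0)
    # S consistent with the final (possibly rescaled) G
    s_list = [update_s(a, g, config.epsilon) for a in multiplex.matrices]
    return FactorizationResult(
        G=g, S=s_list, rse_trace=trace, iterations_run=iterations, config=config
    )


def fuse_pair(
    control: MultiplexNetworks,
    case: MultiplexNetworks,
    config: SolverConfig,
) -> tuple[FactorizationResult, FactorizationResult]:
    """Factorize two conditions from one shared initialization.

    For a differential comparison the two factorizations must live in a
    comparable latent basis: independent initializations let the solver's
    rotational freedom masquerade as biological rewiring.  Both conditions
    are therefore started from the same initial G — the SVD initialization
    of the element-wise mean of the corresponding layers (or one shared
    seeded random draw) — so that differences between the resulting
    integrated networks reflect differences in the data.

    Requires aligned gene indexes and equal layer counts.
    """
    if control.gene_index != case.gene_index:
        raise ValueError("conditions must share one aligned gene index")
    if control.n_layers != case.n_layers:
        raise ValueError("conditions must have the same number of layers")
    if config.init == "svd":
        mean = MultiplexNetworks(
            gene_index=list(control.gene_index),
            matrices=[
                (a + b) / 2.0 for a, b in zip(control.matrices, case.matrices)
            ],
            layer_labels=list(control.layer_labels),
        )
        init = init_svd(mean, config.k)
    else:
        init = init_random(control.n_genes, config.k, seed=config.seed)
    return fuse(control, config, init=init), fuse(case, config, init=init)


def _row_thresholds(w: np.ndarray, top: int) -> np.ndarray:
    """Value of the top-th largest off-diagonal entry of each row."""
    off = np.array(w, copy=True)
    np.fill_diagonal(off, -np.inf)
    return np.sort(off, axis=1)[:, ::-1][:, top - 1]


def _threshold_network(
    w: np.ndarray,
    row_thresh: np.ndarray,
    gene_index: Sequence[str],
    threshold_fraction: float,
    layer_label: str,
) -> ICellNetwork:
    keep = (w >= row_thresh[:, None]) | (w >= row_thresh[None, :])
    keep &= w > 0
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    ii, jj = np.nonzero(np.triu(keep, 1))
    for p, q in zip(ii.tolist(), jj.tolist()):
        e = _norm_edge(gene_index[p], gene_index[q])
        edges.add(e)
        weights[e] = float(w[p, q])
    return ICellNetwork(
        network=GeneNetwork(nodes=list(gene_index), edges=edges,
                            layer_label=layer_label),
        weights=weights,
        threshold_fraction=threshold_fraction,
    )


def build_icell(
    g: np.ndarray,
    gene_index: Sequence[str],
    threshold_fraction: float = 0.01,
    layer_label: str = "icell",
) -> ICellNetwork:
    """Threshold W = G G^T into the integrated network.

    With q = ``threshold_fraction``, a pair (u, v) is kept iff W[u][v] > 0
    and W[u][v] ranks among the ceil(q * (n - 1)) largest off-diagonal
    entries of row u or of row v (the union keeps the result symmetric);
    ties at the row threshold keep all tied values.  All genes remain as
    nodes, so genes whose relationships fall below threshold are isolated,
    not dropped.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    gene_index = list(gene_index)
    n = len(gene_index)
    w = g @ g.T
    np.fill_diagonal(w, 0.0)
    if n < 2:
        return ICellNetwork(
            network=GeneNetwork(nodes=gene_index, edges=set(), layer_label=layer_label),
            weights={},
            threshold_fraction=threshold_fraction,
        )
    top = int(np.ceil(threshold_fraction * (n - 1)))
    row_thresh = _row_thresholds(w, top)
    return _threshold_network(w, row_thresh, gene_index, threshold_fraction,
                              layer_label)


def build_icell_pair(
    g_control: np.ndarray,
    g_case: np.ndarray,
    gene_index: Sequence[str],
    threshold_fraction: float = 0.01,
) -> tuple[ICellNetwork, ICellNetwork]:
    """Threshold two conditions' W = G G^T at common per-row cutoffs.

    The cutoffs are the per-row top-fraction values of the mean of the two
    W matrices, so an edge's presence differs between the two integrated
    networks only where the underlying weights differ — not because the
    cutoff itself moved.  Intended for differential (rewiring) comparisons
    of factorizations produced by :func:`fuse_pair`.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    gene_index = list(gene_index)
    n = len(gene_index)
    if n < 2:
        raise ValueError("need at least two genes")
    w_control = g_control @ g_control.T
    w_case = g_case @ g_case.T
    np.fill_diagonal(w_control, 0.0)
    np.fill_diagonal(w_case, 0.0)
    top = int(np.ceil(threshold_fraction * (n - 1)))
    thresh = _row_thresholds((w_control + w_case) / 2.0, top)
    return (
        _threshold_network(w_control, thresh, gene_index, threshold_fraction,
                           "icell_control"),
        _threshold_network(w_case, thresh, gene_index, threshold_fraction,
                           "icell_case"),
    )


def hard_cluster(g: np.ndarray, gene_index: Sequence[str]) -> Clustering:
    """Assign each gene to the cluster it is closest to in G.

    Gene u goes to argmax_i G[u][i] (1-based); ties break to the lowest
    column index.  All-zero rows go to cluster 1 with a warning.
    """
    if g.ndim != 2 or g.shape[1] < 1:
        raise ValueError("G must have at least one column")
    gene_index = list(gene_index)
    if g.shape[0] != len(gene_index):
        raise ValueError("G rows / gene_index length mismatch")
    zero_rows = np.where(~np.any(g > 0, axis=1))[0]
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero row(s) in G assigned to cluster 1",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = np.argmax(g, axis=1) + 1  # argmax takes the first max: tie rule
    return Clustering(
        assignment={gene: int(lab) for gene, lab in zip(gene_index, labels)},
        k=g.shape[1],
    )
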