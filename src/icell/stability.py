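"""Choosing the number of clusters k by clustering-stability analysis.

With random initial solutions the tri-factorization is non-deterministic:
different runs give similar but non-identical clusterings.  Each run's
hard clustering is encoded in a 0/1 association matrix C (C[i][j] = 1 iff
genes i and j share a cluster); averaging over runs gives C-bar, whose
dispersion measures stability:

    eta_k = var(offdiag(C-bar)) / (p - p^2),     p = (n/k - 1)/(n - 1)
    nu_k  = sum_{i != j} (C-bar(i,j) - 1/k)^2 / (n (n-1) (1/k - 1/k^2))

(population variance).  For identical equal-size clusterings eta_k = 1
for any k, and nu_k = 1 at k = 2 — in general nu equals
(n - k + 1)/(n - 1), which tends to 1 for n >> k.  For independent random
clusterings both tend to 0.  k is chosen where the clusterings are most
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fusion import Clustering, SolverConfig, fuse, hard_cluster
from .net_io import MultiplexNetworks


@dataclass
class AssociationMatrix:
    """n x n co-clustering matrix, entries in [0, 1], diagonal 1."""

    matrix: np.ndarray
    run_count: int = 1

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("association matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("association matrix diagonal must be 1")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("association matrix entries must be in [0, 1]")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class StabilityReport:
    """Dispersion coefficients per candidate k and the chosen k."""

    k_grid: list[int]
    eta: dict[int, float]
    nu: dict[int, float]
    chosen_k: int
    runs: int = 10
    seed: int | None = None


def association_matrix(
    clustering: Clustering, gene_index: Sequence[str]
) -> AssociationMatrix:
    """Single-run association matrix over ``gene_index`` order."""
    labels = clustering.labels(gene_index)
    m = (labels[:, None] == labels[None, :]).astype(float)
    return AssociationMatrix(matrix=m, run_count=1)


def average_association(mats: Sequence[AssociationMatrix]) -> AssociationMatrix:
    if not mats:
        raise ValueError("need at least one association matrix")
    avg = sum(m.matrix for m in mats) / len(mats)
    return AssociationMatrix(matrix=avg, run_count=sum(m.run_count for m in mats))


def dispersion_coefficients(c_bar: AssociationMatrix, k: int) -> tuple[float, float]:
    """(eta_k, nu_k) of an averaged association matrix.

    ``eta_k`` normalizes the population variance of the off-diagonal
    entries by the variance p - p^2 of a Bernoulli(p) entry with
    p = (n/k - 1)/(n - 1) (the off-diagonal mean under identical
    equal-size clusterings); ``nu_k`` measures squared deviation from the
    fully random value 1/k.
    """
    n = c_bar.n
    if not (2 <= k < n):
        raise ValueError("need n > k >= 2")
    m = c_bar.matrix
    off = m[~np.eye(n, dtype=bool)]
    p = (n / k - 1.0) / (n - 1.0)
    denom_eta = p - p * p
    if denom_eta <= 0:
        raise ValueError(f"degenerate (n, k) = ({n}, {k}) for eta")
    eta = float(np.var(off) / denom_eta)  # population variance
    denom_nu = n * (n - 1.0) * (1.0 / k - 1.0 / k**2)
    nu = float(np.sum((off - 1.0 / k) ** 2) / denom_nu)
    return eta, nu


def select_k(
    multiplex: MultiplexNetworks,
    k_grid: Sequence[int],
    runs: int = 10,
    seed: int | None = None,
    max_iter: int = 1000,
    epsilon: float = 1e-10,
    init: str = "acol",
) -> StabilityReport:
    """Evaluate the k grid by repeated random-init runs.

    For each k, ``runs`` factorizations with independent random initial
    solutions (data-driven "acol" draws by default) are hard-clustered,
    their association matrices averaged, and the dispersion coefficients
    computed.  The chosen k maximizes nu_k, with ties broken by larger
    eta_k, then smaller k.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if runs < 2:
        raise ValueError("need runs >= 2")
    master = np.random.default_rng(seed)
    eta: dict[int, float] = {}
    nu: dict[int, float] = {}
    for k in k_grid:
        mats = []
        for run in range(runs):
            run_seed = int(master.integers(2**31 - 1))
            cfg = SolverConfig(
                k=k, max_iter=max_iter, epsilon=epsilon, init=init, seed=run_seed
            )
            try:
                result = fuse(multiplex, cfg)
            except Exception as exc:  # annotate solver failures with (k, run)
                raise RuntimeError(f"solver failed at k={k}, run={run}") from exc
            clustering = hard_cluster(result.G, multiplex.gene_index)
            mats.append(association_matrix(clustering, multiplex.gene_index))
        c_bar = average_association(mats)
        eta[k], nu[k] = dispersion_coefficients(c_bar, k)
    chosen = max(k_grid, key=lambda k: (nu[k], eta[k], -k))
    return StabilityReport(
        k_grid=list(k_grid), eta=eta, nu=nu, chosen_k=chosen, runs=runs, seed=seed
    )
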