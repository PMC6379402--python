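# Methods

## Network fusion (MSNMTF)

All condition-specific layers are 0/1 symmetric adjacency matrices `A_i`
over one shared, lexicographically sorted gene index (union of layer node
sets by default; intersection available).  The objective

```
min_{S, G >= 0}  sum_i || A_i − G S_i G^T ||_F^2
```

is minimized by a fixed-point scheme: each iteration recomputes every
`S_i` by its closed form `(G^T G)^-1 (G^T A_i G) (G^T G)^-1` (a ridge
`epsilon = 1e-10` is added to the Gram diagonal before inversion, and
`S_i` is symmetrized to remove round-off drift), then applies one
multiplicative update to `G`:

```
G <- G ∘ sqrt( sum_i [(A_i G S_i)^+ + G (S_i G^T G S_i)^-]
             / sum_i [(A_i G S_i)^- + G (S_i G^T G S_i)^+] )
```

where `M^+ = (|M|+M)/2`, `M^- = (|M|−M)/2`.  The denominator is guarded
by `epsilon`, so 0/0 positions leave `G` unchanged, and non-negativity is
preserved by construction.  Two orientations of the `(A_i G S_i)` split
are implemented behind `SolverConfig.update_orientation`; the default
("standard", positive part in the numerator) is the orientation derived
from the gradient split and is the one that descends monotonically — the
alternative provably increases the error on test instances and is kept
only for comparison.  The solver runs a fixed budget of `max_iter`
iterations (default 1000, by which the RSE trace has flattened on typical
inputs); an optional early stop (ten consecutive iterations with
|ΔRSE| < 1e-9) is off by default.

**Scale indeterminacy.** `G → G D`, `S_i → D^-1 S_i D^-1` leaves the
objective unchanged for any positive diagonal `D`, so the scale of `G`'s
columns is not identified.  The solver resolves this by returning `G`
with unit-L2-norm columns (compensated in `S_i`).  Without this, the
dominant initialization component inflates one column and skews the
per-row argmax used for hard clustering.

**Initialization.**

* `svd` (default, deterministic): the average adjacency is symmetric, so
  its singular triplets are taken from `eigh` (ordering by |eigenvalue|,
  ties toward the positive one — `numpy.linalg.svd` returns an arbitrary
  basis for degenerate singular values).  Column i of `G_init` is
  `sqrt(sigma_i)` times the larger-norm non-negative part of eigenvector
  i; columns beyond the numerical rank are zero-padded with a warning.
* `acol` (recommended non-deterministic): each column is the mean of 5
  uniformly drawn columns of the average adjacency, plus 1e-6.  Plain
  uniform initialization (`random`, also available) tends to collapse
  columns under the multiplicative updates — runs stall at a visibly
  higher RSE with merged clusters — whereas averaged adjacency columns
  start `G` near distinct neighbourhood profiles while keeping the
  run-to-run variability the stability analysis needs.

**Integrated network.** `W = G G^T` with zeroed diagonal is thresholded
per row: a pair `(u, v)` is kept iff `W[u][v] > 0` and it ranks among the
`ceil(q(n−1))` largest off-diagonal entries of row `u` *or* row `v`
(default `q = 0.01`; the union keeps the result symmetric; ties at the
cutoff are all kept).  All genes stay as nodes, so weakly connected genes
become isolated rather than disappearing.

**Paired (differential) construction.** When two conditions are to be
compared gene-by-gene, independent factorizations are not comparable: the
solver's rotational freedom and razor-thin threshold margins turn
initialization noise into apparent rewiring.  `fuse_pair` therefore
starts both factorizations from one initialization (the SVD of the
element-wise mean of the two conditions' layers), and `build_icell_pair`
thresholds both `W` matrices at common per-row cutoffs computed from
their mean.  With this paired design the planted-rewiring benchmark is
recovered essentially perfectly, while independent constructions leave
the signal below the solver-noise floor at benchmark scale.  Single-
network pipelines are unaffected.

## Choosing k

For each candidate k, `runs` factorizations with `acol` initializations
are hard-clustered; each clustering is encoded as a 0/1 association
matrix (`C[i][j] = 1` iff genes i and j co-cluster) and the matrices are
averaged.  The dispersion coefficients are

```
eta_k = popvar(offdiag(C̄)) / (p − p²),   p = (n/k − 1)/(n − 1)
nu_k  = sum_{i≠j} (C̄(i,j) − 1/k)² / (n(n−1)(1/k − 1/k²))
```

Population (not sample) variance is used in `eta_k`: only then does the
identity case — identical equal-size clusterings — give exactly 1.
`nu_k` equals 1 in that case only at k = 2; in general it equals
`(n−k+1)/(n−1)`, which approaches 1 for n ≫ k.  For independent uniform
random clusterings both coefficients concentrate near `1/runs` (the
entrywise variance of `C̄` is `(1/k)(1−1/k)/runs`), vanishing as `runs`
grows.  The chosen k maximizes `nu_k`, with ties broken by larger
`eta_k`, then smaller k; because `nu_k` mildly rewards any k whose runs
happen to agree, the full `eta/nu` profile is reported and worth
inspecting rather than trusting the argmax alone, especially on small
problems.

## Graphlets

Orbit counts for the 15 orbits of the 2–4-node graphlets are exact
induced counts, computed per node by neighbourhood enumeration with
combinatorial corrections (each 4-node subgraph class is enumerated
through a canonical anchor — middle edge of a path, hub edge of a
diamond, diagonal of a cycle — so every induced subgraph is tallied
once); complexity is O(n·d³) for maximum degree d, no sampling.  The 11
non-redundant orbits are {0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11}; the
redundant {3, 12, 13, 14} are still computed and verified against a
brute-force enumeration oracle in tests.

GDVD weights use dependency counts `o_i = (1, 2, 2, 2, 3, 4, 3, 3, 4, 3,
4, 4, 4, 4, 3)` for orbits 0–14, giving `w_i = 1 − log(o_i)/log(73)`
(`w_0 = 1`; weights non-increasing in `o_i` — both asserted in tests).
Natural logarithms are used throughout (the distance is base-invariant).
The distance is 0 iff the two vectors are equal and is strictly below 1
(per coordinate, `|log(h+1) − log(c+1)| < log(max(h,c)+2)`).

The graphlet correlation matrix appends one artificial all-ones GDV row
before Spearman correlation (average ranks for ties), so orbit columns
that are constant over the real nodes still have defined correlations;
any residual non-finite correlation (possible only in pathological cases)
is set to 0 and the diagonal to 1.  GCD-11 is the Euclidean norm over the
55 strictly-upper-triangle entries of the GCM difference; symmetry and
identity on isomorphic inputs hold, the triangle inequality is not
claimed.

## Random-graph models

All generators emit simple graphs with exactly n nodes, deterministic per
seed, parameterized to match a data network's size and density:

* **ER** hits the target edge count `round(d·n(n−1)/2)` exactly (uniform
  sample of pairs without replacement).
* **ER-DD** stub matching with collision re-shuffling; stubborn
  collisions are repaired by rewiring an existing edge (degree-preserving
  swap); residual stubs are dropped and counted.
* **GEO / GEO-GD** points in the unit cube (dimension 3 by default,
  exposed as a parameter); the radius is set to the m-th smallest
  pairwise distance, hitting the target edge count exactly — no
  bisection needed.  GEO-GD grows positions by duplication (child uniform
  in the ball of radius 2·r0 around its parent, with r0 a provisional
  radius from the uniform-ball density formula, clipped to the cube),
  then runs the same exact-radius GEO edge pass.
* **SF** preferential attachment from a single-edge seed, attachment
  count `max(1, round(d(n−1)/2))`.
* **SF-GD** duplication–divergence: the child inherits the parent's
  neighbours, attaches to the parent with probability p = 0.3 (no value
  is prescribed by the methodology; 0.3 is a conventional choice), and
  loses each shared neighbour with probability q.  The child-side link is
  the one removed, keeping the parent's neighbourhood intact.  q is
  calibrated to the target density by bisection on 3-draw means (density
  decreases in q), then the closest of 5 candidate draws is emitted —
  duplication cascades make single draws noisy, so density is matched in
  expectation (±5%).
* **STICKY** stickiness `theta_i = deg_i / sqrt(sum deg)` from the input
  degree sequence; each pair independent with probability
  `min(1, theta_i·theta_j)`, so `E[deg_i] ≈ deg_i`.

Model fit: 30 replicas per model by default; the real-to-model GCD-11
distances are compared against the `C(30,2)` model-to-model distances by
a two-sided Mann–Whitney U test (normal approximation with tie
correction); p ≤ 0.05 rejects the model as a fit.

## Enrichment statistics

Hypergeometric tails are computed exactly in log-space (log-gamma terms,
compensated summation), stable to backgrounds of tens of thousands of
genes; the enrichment tail is `P(≥X)`, the depletion tail `P(≤X)`, and
they satisfy `P(≥X) + P(≤X−1) = 1` to 1e-12 (which requires allowing X
below the support minimum in the depletion tail, where the probability is
exactly 0).  Fold enrichment `(X/N)/(K/M)` routes fold > 1 to the
enrichment tail and fold ≤ 1 to the depletion tail.  Benjamini–Hochberg
correction is the standard step-up with enforced monotonicity, applied
jointly across all (cluster, term) tests of an annotation source — the
conservative reading when the correction scope is not dictated.  Cluster
size N and background M count only annotated genes; the cluster-quality
metric is the percentage of annotated genes with at least one of their
own annotations enriched (adjusted p ≤ alpha, default 0.05) in their own
cluster.  The enrichment background for rewiring analyses must be named
explicitly by the caller (e.g. always-expressed genes); no default
background is assumed.  `empirical_permutation_p` is the add-one
permutation p-value `(r+1)/(n+1)`.

## Rewiring analysis

Expression calls split the gene universe into four disjoint sets: always
expressed (control ∩ case), always silenced, case-silenced, and
case-activated.  Rewiring scores are computed for a caller-chosen gene
set (typically always-expressed genes) as the GDVD between the gene's
GDVs in the two thresholded integrated networks — not on the raw `W`
weights.  "GDV similarity" is defined as `1 − GDVD`; the pan-condition
score of a gene is its mean pairwise similarity across ≥ 2 integrated
networks, ranked highest (most conserved) first.  Genes absent from a
network's node universe are an error rather than imputed zero — genes
eligible for comparison must appear in both conditions by construction.
Ranking ties break lexicographically by gene id.

## Synthetic data

The generators define the benchmark conditions used throughout the tests:

* `simulate_multiplex(n=150, k=3, m=3, p_in=0.3, p_out=0.02)` — a
  multilayer planted-partition model with one shared partition; the
  cluster-recovery benchmark.  Within/between edge probabilities 0.3/0.02
  give a clear but noisy modular structure (within-cluster degree ≈ 15
  per layer against a background of ≈ 2).
* `simulate_condition_pair(base, n_rewired=10, rewiring_strength=0.8)` —
  the case condition re-routes 80% of each selected gene's incident edges
  per layer to uniformly chosen non-neighbours (degree approximately
  preserved: replacements equal removals; small drift can come from other
  rewired genes touching the same gene).  Rewired genes are always
  expressed in both conditions; optional silencing draws only from the
  non-rewired pool.
* `simulate_annotations(coverage=0.8, noise=0.02)` — terms covering a
  fraction of one cluster plus background noise; the positive control for
  enrichment.

What these fixtures do **not** emulate: heavy-tailed degree
distributions, inter-layer dependence beyond the shared partition,
annotation hierarchies, or the scale of real interactomes (tens of
thousands of genes).  Passing the planted benchmarks shows the machinery
is correct and sensitive under clean modular structure, not that effect
sizes transfer to real data.

## Problem sizes and numerical choices

Tests and examples run at n = 60–300 with 4–10 replicates and solver
budgets of 50–200 iterations (1000 for the descent check) — sizes chosen
so the planted structure is recoverable while the full suite stays fast;
the solver's complexity is O(t·m·k·n²).  Degenerate inputs: all-zero
layers make the RSE undefined (error); all-zero rows of `G` hard-cluster
to cluster 1 with a warning; argmax ties take the lowest column index;
empty edge-set unions give Jaccard 0; an empty intersection of layer node
sets is an error.

## Known limitations

* The multiplicative solver is a local optimizer; from poor
  initializations it stalls at saddle-like fixed points (the motivation
  for `acol` and the SVD init).
* Stability-based selection of k is indecisive between neighbouring k on
  small problems; it was designed for large networks where run-to-run
  variability is informative.
* The integrated network is a co-membership similarity network, not a
  reconstruction of the input adjacency: at low rank its fine structure
  beyond the cluster blocks is not individually meaningful, which is why
  differential comparisons must use the paired construction.
* Graphlet counting is exact but O(n·d³); for networks much denser or
  larger than the intended regime an orbit-counting library with
  asymptotically better combinatorics would be preferable.
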