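"""Network, expression and annotation I/O, plus layer alignment.

Gene identifiers are opaque, case-sensitive strings; no symbol mapping is
performed.  Networks are simple undirected graphs: no self-loops, no
duplicate edges, every edge endpoint is a listed node.  The on-disk formats
are the plain-text ones common in network biology:

* edge lists — two whitespace/tab-separated columns, ``#`` comments allowed;
* expression tables — TSV, first column gene id, one column per tissue,
  cells in ``{0,1}`` (expressed / not expressed calls);
* annotation sets — GMT (term, description, then gene ids, tab-separated);
* gene lists — one id per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class GeneNetwork:
    """A simple undirected gene–gene network.

    Parameters
    ----------
    nodes
        Ordered gene identifiers.  Order is preserved (first-appearance
        order for networks read from disk).
    edges
        Set of unordered gene-id pairs, stored as sorted 2-tuples.
    layer_label
        Free-text label of the data layer (e.g. ``"ppi"``, ``"coex"``).
    """

    nodes: list[str]
    edges: set[tuple[str, str]]
    layer_label: str = ""

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u > v:
                raise ValueError(f"edge {(u, v)!r} not in canonical order")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint missing from node list: {(u, v)!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_sets(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {u: set() for u in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degree(self) -> dict[str, int]:
        return {u: len(nbrs) for u, nbrs in self.adjacency_sets().items()}

    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    def has_edge(self, u: str, v: str) -> bool:
        return _norm_edge(u, v) in self.edges

    def to_numpy(self, index: Sequence[str] | None = None) -> np.ndarray:
        """Dense 0/1 adjacency matrix over ``index`` (default: own nodes)."""
        idx = list(self.nodes) if index is None else list(index)
        pos = {g: i for i, g in enumerate(idx)}
        a = np.zeros((len(idx), len(idx)), dtype=float)
        for u, v in self.edges:
            if u in pos and v in pos:
                a[pos[u], pos[v]] = 1.0
                a[pos[v], pos[u]] = 1.0
        return a

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] | None = None,
        layer_label: str = "",
    ) -> "GeneNetwork":
        """Build a network from raw (possibly duplicated/looped) edge pairs.

        Self-loops are dropped and reversed duplicates collapsed; the node
        order is first-appearance order of ``nodes`` then edge endpoints.
        """
        ordered: list[str] = []
        seen: set[str] = set()
        for g in nodes or ():
            if g not in seen:
                seen.add(g)
                ordered.append(g)
        edge_set: set[tuple[str, str]] = set()
        for u, v in edges:
            for g in (u, v):
                if g not in seen:
                    seen.add(g)
                    ordered.append(g)
            if u != v:
                edge_set.add(_norm_edge(u, v))
        return cls(nodes=ordered, edges=edge_set, layer_label=layer_label)


@dataclass
class ExpressionProfile:
    """Binary expression calls: tissue -> set of expressed gene ids."""

    calls: dict[str, set[str]] = field(default_factory=dict)

    def expressed_in(self, tissue: str) -> set[str]:
        return self.calls[tissue]

    @property
    def tissues(self) -> list[str]:
        return list(self.calls)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.calls.values():
            out |= s
        return out


@dataclass
class MultiplexNetworks:
    """m aligned symmetric adjacency matrices over one shared gene index."""

    gene_index: list[str]
    matrices: list[np.ndarray]
    layer_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.gene_index)
        for label, a in zip(self.layer_labels, self.matrices):
            if a.shape != (n, n):
                raise ValueError(f"layer {label!r}: shape {a.shape} != ({n}, {n})")
            if np.any(np.diag(a) != 0):
                raise ValueError(f"layer {label!r}: nonzero diagonal")
            if not np.array_equal(a, a.T):
                raise ValueError(f"layer {label!r}: adjacency not symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_layers(self) -> int:
        return len(self.matrices)

    def layer_network(self, i: int) -> GeneNetwork:
        """Recover layer ``i`` as a :class:`GeneNetwork`."""
        a = self.matrices[i]
        ii, jj = np.nonzero(np.triu(a, 1))
        edges = {
            _norm_edge(self.gene_index[p], self.gene_index[q])
            for p, q in zip(ii.tolist(), jj.tolist())
        }
        return GeneNetwork(
            nodes=list(self.gene_index), edges=edges, layer_label=self.layer_labels[i]
        )


class EdgeListParseError(ValueError):
    """Raised for a malformed edge-list line; carries the line number."""


def read_edge_list(path: str | Path, layer_label: str = "") -> GeneNetwork:
    """Read a 2-column edge list.

    Lines starting with ``#`` are comments; blank lines are skipped.  A line
    with fewer than two whitespace-separated fields is a parse error naming
    the line number.  Extra columns (e.g. weights) are ignored.  An empty
    file yields an empty network.
    """
    path = Path(path)
    raw_edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=2 fields, got {len(fields)}"
                )
            raw_edges.append((fields[0], fields[1]))
    return GeneNetwork.from_edges(raw_edges, layer_label=layer_label or path.stem)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write the network as a sorted 2-column TSV edge list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# layer: {net.layer_label}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression_table(path: str | Path) -> ExpressionProfile:
    """Read a binary gene x tissue expression table (TSV)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: expected a gene column plus >=1 tissue column")
        tissues = header[1:]
        calls: dict[str, set[str]] = {t: set() for t in tissues}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: column count mismatch")
            gene = fields[0]
            for t, cell in zip(tissues, fields[1:]):
                if cell not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: expression call {cell!r} not in {{0,1}}")
                if cell == "1":
                    calls[t].add(gene)
    return ExpressionProfile(calls=calls)


def write_expression_table(
    profile: ExpressionProfile, genes: Sequence[str], path: str | Path
) -> None:
    path = Path(path)
    tissues = profile.tissues
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(tissues) + "\n")
        for g in genes:
            cells = ["1" if g in profile.calls[t] else "0" for t in tissues]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation sets in GMT format: term, description, gene ids."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            terms[fields[0]] = set(fields[2:])
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path) -> list[str]:
    """Write annotation sets as GMT; empty terms are skipped and returned."""
    path = Path(path)
    skipped: list[str] = []
    with path.open("w") as fh:
        for term, genes in terms.items():
            gene_list = sorted(set(genes))
            if not gene_list:
                skipped.append(term)
                continue
            fh.write(term + "\t-\t" + "\t".join(gene_list) + "\n")
    return skipped


def read_gene_list(path: str | Path) -> list[str]:
    path = Path(path)
    genes: list[str] = []
    with path.open() as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


def make_tissue_specific(net: GeneNetwork, expressed: set[str]) -> GeneNetwork:
    """Induced subnetwork on the genes expressed in one tissue.

    Keeps a node iff it is expressed, and an edge iff both endpoints are.
    Idempotent; an empty intersection yields an empty network.
    """
    kept_nodes = [g for g in net.nodes if g in expressed]
    kept_edges = {e for e in net.edges if e[0] in expressed and e[1] in expressed}
    return GeneNetwork(nodes=kept_nodes, edges=kept_edges, layer_label=net.layer_label)


def filter_to_anchor_layer(
    nets: Sequence[GeneNetwork], anchor: int = 0
) -> list[GeneNetwork]:
    """Keep, in every layer, only the genes present in the anchor layer.

    Emulates restricting the analysis to genes with at least one reported
    interaction in a designated reference layer (default: the first).
    """
    anchor_nodes = set(nets[anchor].nodes)
    return [make_tissue_specific(net, anchor_nodes) for net in nets]


def align_networks(
    nets: Sequence[GeneNetwork], node_policy: str = "union"
) -> MultiplexNetworks:
    """Put several layers onto one shared gene index.

    The shared index is sorted lexicographically so runs are reproducible
    regardless of input row order.  With ``node_policy="union"`` absent
    genes appear as isolated rows; with ``"intersection"`` every layer is
    restricted to the common gene set (an empty intersection is an error).
    """
    if not nets:
        raise ValueError("need at least one network")
    if node_policy == "union":
        shared: set[str] = set()
        for net in nets:
            shared |= set(net.nodes)
    elif node_policy == "intersection":
        shared = set(nets[0].nodes)
        for net in nets[1:]:
            shared &= set(net.nodes)
        if not shared:
            raise ValueError("intersection of layer node sets is empty")
    else:
        raise ValueError(f"unknown node_policy {node_policy!r}")
    gene_index = sorted(shared)
    matrices = [net.to_numpy(gene_index) for net in nets]
    labels = [net.layer_label or f"layer{i}" for i, net in enumerate(nets)]
    return MultiplexNetworks(gene_index=gene_index, matrices=matrices, layer_labels=labels)


def edge_jaccard(net1: GeneNetwork, net2: GeneNetwork) -> float:
    """Jaccard index of the two edge sets (unordered pairs).

    Returns 0.0 when the union is empty (two edgeless networks).
    """
    union = net1.edges | net2.edges
    if not union:
        return 0.0
    return len(net1.edges & net2.edges) / len(union)


def union_network(nets: Sequence[GeneNetwork], layer_label: str = "union") -> GeneNetwork:
    """Merge layers by taking the union of node sets and edge sets."""
    if not nets:
        raise ValueError("need at least one network")
    nodes: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for net in nets:
        for g in net.nodes:
            if g not in seen:
                seen.add(g)
                nodes.append(g)
        edges |= net.edges
    return GeneNetwork(nodes=nodes, edges=edges, layer_label=layer_label)
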