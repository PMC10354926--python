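"""Interaction networks: loading, largest connected component, signature
modules and multi-source hop-distance fields.

The interactome is an undirected simple graph over protein/gene identifiers
(a PPI edge list or PSI-MI TAB export).  When no curated network is
available, a co-expression network is built from the single-cell matrix:
gene pairs are connected when the two-sided p-value of their Pearson
correlation across cells falls below a threshold (0.05 by default, no
multiple-testing correction).

Distances are unweighted hop counts.  All proximity computations run on the
largest connected component (LCC), where every distance is finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .io import ExpressionMatrix, GeneIdMapping, map_gene_ids
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "NetworkModule",
    "DistanceField",
    "load_network",
    "write_edge_list",
    "largest_connected_component",
    "build_coexpression_network",
    "induce_module",
    "multi_source_distance_field",
]


@dataclass
class InteractionNetwork:
    """Undirected simple graph over node identifiers.

    ``is_lcc`` marks a graph that is a (connected) largest connected
    component; only such graphs support distance fields.  The CSR adjacency
    and the node indexing are built lazily and cached.
    """

    graph: nx.Graph
    is_lcc: bool = False
    _nodes: Optional[list[str]] = field(default=None, repr=False)
    _index: Optional[dict[str, int]] = field(default=None, repr=False)
    _adjacency: Optional[scipy.sparse.csr_matrix] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in a fixed (sorted) order."""
        if self._nodes is None:
            self._nodes = sorted(self.graph.nodes)
        return self._nodes

    @property
    def node_index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(self.nodes)}
        return self._index

    @property
    def adjacency(self) -> scipy.sparse.csr_matrix:
        """Boolean CSR adjacency in ``nodes`` order."""
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self.graph, nodelist=self.nodes, format="csr", dtype=np.int8)
        return self._adjacency


@dataclass
class NetworkModule:
    """The subset of a signature's genes found in the network LCC."""

    owner_id: str
    nodes: frozenset[str]
    original_size: int

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class DistanceField:
    """min-over-sources hop distance from one module to every LCC node."""

    source_module_id: str
    network: InteractionNetwork
    distances: np.ndarray  # int hop counts, aligned with network.nodes

    def __getitem__(self, node: str) -> int:
        return int(self.distances[self.network.node_index[node]])

    def mean_over(self, nodes: Sequence[str]) -> float:
        idx = [self.network.node_index[n] for n in nodes]
        return float(self.distances[idx].mean())


def _simple_graph(edges: list[tuple[str, str]]) -> tuple[nx.Graph, int]:
    g = nx.Graph()
    n_loops = 0
    for u, v in edges:
        if u == v:
            n_loops += 1
            continue
        g.add_edge(u, v)
    return g, n_loops


def load_network(path: str | Path, format: str | None = None) -> InteractionNetwork:
    """Read an undirected network from a two-column edge list or PSI-MI TAB.

    Edge lists are tab-separated with two id columns (extra columns are
    ignored).  PSI-MI TAB 2.5/2.7 rows use interactor columns 1–2 with
    database prefixes such as ``uniprotkb:`` stripped.  The result is a
    deduplicated simple graph; self-loops are removed and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    if format is None:
        format = "psimitab" if path.suffix in (".mitab", ".txt25", ".psimitab") else "edge_list"
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if format == "edge_list":
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}: malformed edge-list line {lineno}")
                edges.append((parts[0], parts[1]))
            elif format == "psimitab":
                if len(parts) < 15:
                    raise ValueError(
                        f"{path}: malformed PSI-MI TAB line {lineno} "
                        f"({len(parts)} columns, expected >= 15)")
                a = parts[0].split(":", 1)[-1]
                b = parts[1].split(":", 1)[-1]
                if not a or not b:
                    raise ValueError(f"{path}: empty interactor id on line {lineno}")
                edges.append((a, b))
            else:
                raise ValueError(f"unknown network format {format!r}")
    g, n_loops = _simple_graph(edges)
    if n_loops:
        logger.info("removed %d self-loop(s) from %s", n_loops, path.name)
    if g.number_of_nodes() == 0:
        raise ValueError(f"network file {path} yields an empty graph")
    return InteractionNetwork(g, is_lcc=nx.is_connected(g))


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Export as a two-column TSV edge list (sorted, deterministic)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """The connected subgraph with the most nodes.

    Ties are broken by keeping the component containing the
    lexicographically smallest node id, so the result is deterministic.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot take the LCC of an empty graph")
    comps = list(nx.connected_components(net.graph))
    best_size = max(len(c) for c in comps)
    winners = [c for c in comps if len(c) == best_size]
    comp = min(winners, key=lambda c: min(c))
    frac = 100.0 * len(comp) / net.graph.number_of_nodes()
    logger.info("LCC retains %d/%d nodes (%.1f%%)", len(comp),
                net.graph.number_of_nodes(), frac)
    return InteractionNetwork(net.graph.subgraph(comp).copy(), is_lcc=True)


def pearson_pvalues(values: np.ndarray) -> np.ndarray:
    """Two-sided p-value matrix of pairwise Pearson correlations.

    Rows are variables (genes), columns observations (cells).  Uses the
    t-distribution transform t = r·sqrt(N−2)/sqrt(1−r²) with N−2 degrees of
    freedom.  Diagonal is set to 1 (self-pairs are never edges).
    """
    n_obs = values.shape[1]
    if n_obs < 3:
        raise ValueError("Pearson p-values need at least 3 observations")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_obs - 2) / (1.0 - r ** 2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n_obs - 2)
    p[~np.isfinite(t)] = 0.0  # |r| = 1 → p = 0
    np.fill_diagonal(p, 1.0)
    return p


def build_coexpression_network(sc: ExpressionMatrix, alpha: float = 0.05,
                               gene_universe: Optional[Sequence[str]] = None,
                               ) -> InteractionNetwork:
    """Binary co-expression network from a single-cell matrix.

    Gene i and gene j are connected iff the two-sided p-value of their
    Pearson correlation across cells is below ``alpha``.  Genes with zero
    variance (correlation undefined) are excluded; ``gene_universe``
    restricts the candidate genes, bounding the quadratic cost.
    """
    if sc.data.shape[1] < 3:
        raise ValueError("co-expression network needs at least 3 cells")
    df = sc.data
    if gene_universe is not None:
        df = df.loc[df.index.intersection(list(dict.fromkeys(gene_universe)))]
    values = df.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info("co-expression: excluding %d zero-variance gene(s)", n_dropped)
    df = df.loc[variable]
    values = values[variable]
    genes = df.index.to_numpy()
    if len(genes) < 2:
        raise ValueError("fewer than 2 variable genes; cannot build network")
    p = pearson_pvalues(values)
    ii, jj = np.nonzero(np.triu(p < alpha, k=1))
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(zip(genes[ii], genes[jj]))
    logger.info("co-expression network: %d genes, %d edges (alpha=%g)",
                g.number_of_nodes(), g.number_of_edges(), alpha)
    if g.number_of_edges() == 0:
        raise ValueError("co-expression network has no edges at this threshold")
    return InteractionNetwork(g, is_lcc=nx.is_connected(g))


def induce_module(signature: GeneSignature, lcc: InteractionNetwork,
                  mapping: Optional[GeneIdMapping] = None) -> NetworkModule:
    """Intersect a (mapped) signature with the LCC node set."""
    if not lcc.is_lcc:
        raise ValueError("modules must be induced in the largest connected component")
    genes = map_gene_ids(signature.genes, mapping)
    nodes = frozenset(genes) & frozenset(lcc.nodes)
    return NetworkModule(owner_id=signature.owner_id, nodes=nodes,
                         original_size=signature.size)


def multi_source_distance_field(lcc: InteractionNetwork,
                                module: NetworkModule) -> DistanceField:
    """Hop distance from the nearest module node, for every LCC node.

    Computed as one multi-source breadth-first search (min-only Dijkstra on
    the unweighted adjacency), so the field equals the pointwise minimum of
    single-source BFS distances from each module node.
    """
    if not lcc.is_lcc:
        raise ValueError("distance fields require a connected LCC")
    if module.size == 0:
        raise ValueError(
            f"signature {module.owner_id!r} has no network support (empty module)")
    idx = [lcc.node_index[n] for n in module.nodes]
    dist = scipy.sparse.csgraph.dijkstra(
        lcc.adjacency, directed=False, indices=idx, unweighted=True, min_only=True)
    return DistanceField(source_module_id=module.owner_id, network=lcc,
                         distances=dist.astype(np.int64))
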