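"""Simple undirected networks: generators, I/O, and connectivity profiles.

All dynamics in this package run on simple, connected, undirected,
unweighted graphs with contiguous 0-based integer node labels.  The
:class:`Network` container keeps the adjacency matrix in sparse CSR form
so that the coupling operators built from it (Laplacian, bi-Laplacian)
inherit a sparse-friendly representation.

Two synthetic topologies cover the study conditions used throughout:
scale-free Barabási–Albert graphs (heterogeneous degrees, hubs) and
Erdős–Rényi graphs (narrow, Poisson-like degree distribution).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "ConnectivityProfile",
    "generate_ba",
    "generate_er",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "connectivity_profile",
    "single_node_network",
]


class MalformedInputError(ValueError):
    """An edge-list or GraphML file violates the format contract."""


@dataclass(frozen=True)
class Network:
    """A simple undirected graph with nodes labelled 0..N-1.

    Parameters
    ----------
    node_count
        Number of nodes N.
    adjacency
        Symmetric binary CSR matrix with zero diagonal.
    node_map
        Optional mapping original-label -> 0-based index, recorded when a
        reader had to relabel nodes (giant-component extraction, arbitrary
        ids in a file).
    """

    node_count: int
    adjacency: sp.csr_array
    node_map: dict | None = None
    # per-instance scratch cache for operators/spectra; excluded from
    # equality and hashing on purpose
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (self.node_count, self.node_count):
            raise ValueError("adjacency shape does not match node_count")
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        data = a.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("adjacency entries must be 0/1")

    @property
    def degrees(self) -> np.ndarray:
        """Integer degree vector k (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def edge_count(self) -> int:
        return self.adjacency.nnz // 2

    def edges(self) -> np.ndarray:
        """(E, 2) array of edges with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def to_networkx(self) -> nx.Graph:
        g = nx.from_scipy_sparse_array(self.adjacency)
        return g

    def is_connected(self) -> bool:
        n_comp = sp.csgraph.connected_components(
            self.adjacency, directed=False, return_labels=False
        )
        return n_comp == 1


@dataclass(frozen=True)
class ConnectivityProfile:
    """First- and second-order connectivity of every node.

    ``k`` is the degree, ``k2`` the two-jump degree (distinct nodes at
    shortest-path distance exactly 2) and ``s`` the two-walk count
    ``sum_j A_ij k_j``.  On a tree s = k + k2 exactly; triangles and
    shared neighbours make s exceed k2 + (walks closed back to distance-1
    nodes).
    """

    k: np.ndarray
    k2: np.ndarray
    s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": np.arange(len(self.k)), "k": self.k, "k2": self.k2, "s": self.s}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _network_from_nx(g: nx.Graph, node_map: dict | None = None) -> Network:
    a = nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes), format="csr", dtype=float)
    a = sp.csr_array(a)
    return Network(node_count=g.number_of_nodes(), adjacency=a, node_map=node_map)


def single_node_network() -> Network:
    """The degenerate N=1 network (no edges, zero Laplacian).

    Used as an exact scalar oracle: all coupling operators vanish, so the
    dynamics reduce to the on-node nonlinearity.
    """
    return Network(node_count=1, adjacency=sp.csr_array((1, 1)))


def generate_ba(n: int, m: int, seed: int) -> Network:
    """Grow a Barabási–Albert scale-free graph with preferential attachment.

    Seed convention: for m = 1 growth starts from a single edge on nodes
    {0, 1}; for m > 1 from a clique on nodes 0..m.  Each subsequent node
    attaches to m distinct existing nodes drawn with probability
    proportional to current degree (draws without replacement).  The same
    (n, m, seed) always produces the same edge set.

    Parameters
    ----------
    n
        Final number of nodes; must exceed m.
    m
        Edges added per new node (m = 1 grows a tree).
    seed
        Seed for the attachment draws.
    """
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError("m must be a positive integer")
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int]] = []
    # repeated-node list: node i appears deg(i) times, so uniform draws
    # from it realize preferential attachment
    repeated: list[int] = []
    if m == 1:
        edges.append((0, 1))
        repeated.extend([0, 1])
        start = 2
    else:
        for i in range(m + 1):
            for j in range(i + 1, m + 1):
                edges.append((i, j))
        for i in range(m + 1):
            repeated.extend([i] * m)
        start = m + 1
    pool = np.array(repeated, dtype=np.int64)
    for new in range(start, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(int(pool[rng.integers(pool.size)]))
        tlist = sorted(targets)
        for t in tlist:
            edges.append((t, new))
        pool = np.concatenate([pool, np.array(tlist, dtype=np.int64), np.full(m, new)])
    return _edges_to_network(n, edges)


def generate_er(n: int, mean_degree: float, seed: int) -> Network:
    """Draw an Erdős–Rényi graph G(n, p) with p = mean_degree / (n - 1).

    If the draw is disconnected, the giant component is kept and relabelled
    0..N'-1 (the reduction is logged); the dynamics require a single
    connected system.
    """
    if not (0 < mean_degree <= n - 1):
        raise ValueError(f"mean_degree must lie in (0, n-1], got {mean_degree}")
    p = mean_degree / (n - 1)
    g = nx.gnp_random_graph(n, p, seed=int(seed))
    if not nx.is_connected(g):
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant)
        mapping = {old: new for new, old in enumerate(sorted(g.nodes))}
        logger.info(
            "ER draw (n=%d, p=%.4g, seed=%d) disconnected; keeping giant "
            "component with %d nodes",
            n,
            p,
            seed,
            len(giant),
        )
        g = nx.relabel_nodes(g, mapping)
        return _network_from_nx(g, node_map=mapping)
    return _network_from_nx(g)


def _edges_to_network(n: int, edges: list[tuple[int, int]]) -> Network:
    rows = np.array([e[0] for e in edges] + [e[1] for e in edges])
    cols = np.array([e[1] for e in edges] + [e[0] for e in edges])
    a = sp.csr_array(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    a.data[:] = 1.0  # collapse duplicates
    return Network(node_count=n, adjacency=a)


def read_edge_list(path: str | Path, sidecar: bool = True) -> Network:
    """Read a whitespace-separated edge list ('#' comments, 0-based ids).

    Duplicate and reversed pairs collapse to a single undirected edge;
    self-loops are rejected.  Non-contiguous or non-zero-based ids are
    relabelled in sorted order and, when ``sidecar`` is true, the mapping
    is persisted next to the input as ``<path>.nodes.csv``.  A warning is
    emitted if the resulting graph is disconnected.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected two tokens, got {len(tokens)}"
                )
            try:
                i, j = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise MalformedInputError(
                    f"{path}:{lineno}: non-integer token in {tokens!r}"
                ) from exc
            if i == j:
                raise MalformedInputError(f"{path}:{lineno}: self-loop on node {i}")
            pairs.append((min(i, j), max(i, j)))
    if not pairs:
        raise MalformedInputError(f"{path}: no edges found")
    ids = sorted({v for e in pairs for v in e})
    node_map = None
    if ids != list(range(len(ids))):
        node_map = {old: new for new, old in enumerate(ids)}
        pairs = [(node_map[i], node_map[j]) for i, j in pairs]
        if sidecar:
            pd.DataFrame(
                {"original_id": list(node_map), "index": list(node_map.values())}
            ).to_csv(path.with_suffix(path.suffix + ".nodes.csv"), index=False)
    n = len(ids)
    net = _edges_to_network(n, pairs)
    net = Network(node_count=n, adjacency=net.adjacency, node_map=node_map)
    if not net.is_connected():
        warnings.warn(f"{path}: graph is not connected", stacklevel=2)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write one 'i j' pair per line (i < j, 0-based)."""
    with open(path, "w") as fh:
        fh.write(f"# nodes: {net.node_count}, edges: {net.edge_count}\n")
        for i, j in net.edges():
            fh.write(f"{i} {j}\n")


def read_graphml(path: str | Path) -> Network:
    """Read a GraphML file; nodes are relabelled 0..N-1 in sorted order."""
    g = nx.read_graphml(path)
    if g.is_directed() or g.is_multigraph():
        raise MalformedInputError(f"{path}: only simple undirected graphs supported")
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    def _key(v):
        try:
            return (0, int(v))
        except (TypeError, ValueError):
            return (1, str(v))

    mapping = {old: new for new, old in enumerate(sorted(g.nodes, key=_key))}
    g = nx.relabel_nodes(g, mapping)
    net = _network_from_nx(g, node_map=mapping)
    if not net.is_connected():
        warnings.warn(f"{path}: graph is not connected", stacklevel=2)
    return net


def connectivity_profile(net: Network) -> ConnectivityProfile:
    """Compute per-node degree k, two-jump degree k2, and two-walk count s.

    k2 counts *distinct* nodes at shortest-path distance exactly 2 (a
    breadth-first quantity), while s counts two-step walks with
    multiplicity; the two coincide (after removing the degree) only on
    triangle-free graphs without shared neighbours, i.e. trees.
    """
    a = net.adjacency
    k = net.degrees
    s = np.rint(a @ k.astype(float)).astype(int)
    a2 = sp.csr_array(a @ a)  # (A^2)_ij = number of 2-walks i -> j
    a2 = a2 - sp.diags_array(a2.diagonal(), format="csr")
    # distance exactly 2: reachable in two steps but not adjacent
    dist2 = a2 - a2.multiply(a)
    k2 = np.asarray((dist2 > 1e-9).sum(axis=1)).ravel().astype(int)
    return ConnectivityProfile(k=k, k2=k2, s=s)
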