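"""Markov Clustering (MCL) on weighted similarity graphs.

MCL partitions a graph by simulating random-walk flow: the column-stochastic
transition matrix is alternately *expanded* (matrix power, default square)
and *inflated* (entrywise power with exponent IF followed by column
renormalisation).  Expansion lets flow spread along the graph; inflation
sharpens it, so flow condenses within natural clusters.  The inflate factor
(IF) controls granularity: larger IF gives more, smaller clusters.

The implementation is sparse throughout (memory proportional to edges) and
deterministic for a fixed input graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "WeightedGraph",
    "MclParams",
    "Partition",
    "mcl",
    "if_sweep",
    "stable_range",
    "read_abc",
    "write_abc",
]


@dataclass
class WeightedGraph:
    """Undirected weighted graph over hashable vertex ids.

    Edges are ``(u, v, weight)`` with ``weight >= 0``; self-edges are
    rejected on input (MCL adds its own self-loops).
    """

    vertex_ids: list
    edges: list[tuple]

    def __post_init__(self) -> None:
        seen = set(self.vertex_ids)
        if len(seen) != len(self.vertex_ids):
            raise ValueError("duplicate vertex ids")
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"invalid weight {w!r} on edge ({u!r}, {v!r})")
            if u not in seen or v not in seen:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown vertex")

    @property
    def n(self) -> int:
        return len(self.vertex_ids)

    def to_sparse(self) -> sp.csr_matrix:
        """Symmetric adjacency matrix in the order of ``vertex_ids``."""
        index = {v: i for i, v in enumerate(self.vertex_ids)}
        n = self.n
        rows, cols, data = [], [], []
        for u, v, w in self.edges:
            i, j = index[u], index[v]
            rows += [i, j]
            cols += [j, i]
            data += [float(w), float(w)]
        mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=float)
        mat.sum_duplicates()
        return mat

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        g.add_weighted_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "WeightedGraph":
        edges = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
        return cls(list(g.nodes), edges)


@dataclass(frozen=True)
class MclParams:
    inflate_factor: float = 2.0
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflate_factor <= 1:
            raise ValueError("inflate factor must be > 1")
        if self.expansion_power < 2:
            raise ValueError("expansion power must be >= 2")


@dataclass
class Partition:
    """Result of one MCL run: a total assignment vertex_id -> cluster_id.

    Cluster ids are consecutive integers ordered by each cluster's smallest
    vertex index, so partitions are comparable across runs.
    """

    inflate_factor: float
    assignment: dict
    converged: bool = True
    iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[list]:
        out: dict[int, list] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, []).append(v)
        return [out[c] for c in sorted(out)]


def _normalize_columns(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags(1.0 / sums)


def _add_self_loops(adj: sp.csr_matrix) -> sp.csc_matrix:
    """Self-loop weight = each vertex's maximum incident weight (1.0 for
    isolated vertices), standard MCL practice."""
    n = adj.shape[0]
    loops = np.asarray(adj.max(axis=1).todense()).ravel() if adj.nnz else np.zeros(n)
    loops[loops <= 0] = 1.0
    return (adj + sp.diags(loops)).tocsc()


def _iterate(m: sp.csc_matrix, params: MclParams) -> tuple[sp.csc_matrix, bool, int]:
    tol = params.convergence_tol
    for it in range(1, params.max_iterations + 1):
        prev = m
        m = m ** params.expansion_power          # expansion
        m = m.power(params.inflate_factor)       # inflation (entrywise)
        m = _normalize_columns(m)
        if params.prune_threshold > 0:
            m.data[m.data < params.prune_threshold] = 0.0
            m.eliminate_zeros()
            m = _normalize_columns(m)
        delta = abs(m - prev)
        if delta.nnz == 0 or delta.max() < tol:
            return m, True, it
    return m, False, params.max_iterations


def _extract_clusters(m: sp.csc_matrix, vertex_ids: list) -> dict:
    """Clusters from the converged matrix.

    Attractors are vertices with positive diagonal mass; attractor systems
    (rows that overlap) are merged into one cluster; every vertex joins the
    cluster receiving the largest share of its column mass (ties toward the
    smaller cluster id).
    """
    n = m.shape[0]
    csr = m.tocsr()
    diag = csr.diagonal()
    attractors = np.where(diag > 0)[0]
    if attractors.size == 0:                      # degenerate; treat all rows
        attractors = np.unique(csr.nonzero()[0])
    # attractor systems: attractors mutually supporting each other (nonzero
    # flow between attractor columns) form one cluster nucleus
    block = csr[attractors, :][:, attractors]
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(attractors)))
    coo = block.tocoo()
    for r, c, w in zip(coo.row, coo.col, coo.data):
        if r != c and w > 0:
            g.add_edge(r, c)
    systems = [sorted(c) for c in nx.connected_components(g)]
    systems.sort(key=lambda s: attractors[s[0]])
    # attraction mass of each vertex toward each system
    mass = np.zeros((len(systems), n))
    rows_csr = csr[attractors, :].toarray() if n else np.zeros((0, n))
    for k, system in enumerate(systems):
        mass[k] = rows_csr[system].sum(axis=0)
    assignment_idx = np.zeros(n, dtype=int)
    for j in range(n):
        col = mass[:, j]
        if col.max() <= 0:
            # no attraction (can only happen on fully pruned columns);
            # fall back to the vertex's own singleton cluster
            assignment_idx[j] = -1
        else:
            assignment_idx[j] = int(np.flatnonzero(col == col.max())[0])
    # relabel clusters by smallest member index; singletons for -1
    raw: dict[int, list[int]] = {}
    next_singleton = len(systems)
    for j, k in enumerate(assignment_idx):
        if k == -1:
            raw[next_singleton] = [j]
            next_singleton += 1
        else:
            raw.setdefault(k, []).append(j)
    ordered = sorted(raw.values(), key=lambda members: members[0])
    assignment = {}
    for cid, members in enumerate(ordered):
        for j in members:
            assignment[vertex_ids[j]] = cid
    return assignment


def mcl(graph: WeightedGraph, params: MclParams | None = None) -> Partition:
    """Run MCL on ``graph`` and return the resulting :class:`Partition`.

    Clusters never span disconnected components of the input graph; column
    stochasticity is restored after every inflation; non-convergence within
    ``max_iterations`` is reported via ``Partition.converged``.
    """
    params = params or MclParams()
    if graph.n == 0:
        raise ValueError("empty graph")
    adj = graph.to_sparse()
    m = _normalize_columns(_add_self_loops(adj))
    m, converged, iters = _iterate(m, params)
    assignment = _extract_clusters(m, graph.vertex_ids)
    return Partition(
        inflate_factor=params.inflate_factor,
        assignment=assignment,
        converged=converged,
        iterations=iters,
    )


def if_sweep(
    graph: WeightedGraph, if_values, params: MclParams | None = None
) -> list[tuple[float, int]]:
    """Run MCL at each inflate factor; returns ``[(IF, n_clusters), ...]``
    in input order."""
    base = params or MclParams()
    out = []
    for f in if_values:
        p = MclParams(
            inflate_factor=f,
            expansion_power=base.expansion_power,
            prune_threshold=base.prune_threshold,
            max_iterations=base.max_iterations,
            convergence_tol=base.convergence_tol,
        )
        out.append((f, mcl(graph, p).n_clusters))
    return out


def stable_range(sweep: list[tuple[float, int]]) -> tuple[float, float, int]:
    """Longest maximal run of consecutive inflate factors with an identical
    cluster count; ties broken toward the lower-IF run.

    Mirrors choosing the granularity plateau of an IF sweep (e.g. a cluster
    count that stays constant across a range of inflate factors).
    """
    if not sweep:
        raise ValueError("empty sweep")
    best = None  # (length, start_index)
    i = 0
    while i < len(sweep):
        j = i
        while j + 1 < len(sweep) and sweep[j + 1][1] == sweep[i][1]:
            j += 1
        length = j - i + 1
        if best is None or length > best[0]:
            best = (length, i)
        i = j + 1
    _, start = best
    end = start + best[0] - 1
    return (sweep[start][0], sweep[end][0], sweep[start][1])


def read_abc(path) -> WeightedGraph:
    """Read an edge list in the ABC format (``src<TAB>dst<TAB>weight``)."""
    vertices: list = []
    seen = set()
    edges = []
    pair_seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2-3 fields")
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) == 3 else 1.0
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    vertices.append(x)
            if u == v:
                continue
            key = (u, v) if u <= v else (v, u)
            if key in pair_seen:
                continue
            pair_seen.add(key)
            edges.append((u, v, w))
    return WeightedGraph(vertices, edges)


def write_abc(graph: WeightedGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, w in graph.edges:
            fh.write(f"{u}\t{v}\t{w:g}\n")


def write_partition(partition: Partition, path) -> None:
    """One line per cluster: ``cluster_id<TAB>vertex<TAB>vertex...``."""
    with open(path, "w") as fh:
        for cid, members in enumerate(partition.clusters()):
            fh.write("\t".join([str(cid)] + [str(m) for m in members]) + "\n")
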