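"""Interaction-network sub-module extraction and topology analysis.

The centrepiece is a node-weighted Steiner-tree approximation in the
Klein-Ravi spider-merge style: starting from one singleton tree per seed
("terminal") gene, the algorithm repeatedly selects the centre node v and
subset S of at least two current trees minimising the ratio

    ( w(v) + sum_{t in S} dist(v, t) ) / |S|

where dist(v, t) is the cheapest node-weighted path cost from v to tree t
(interior nodes only; nodes already bought by any tree cost 0), and merges
S along those paths.  The loop stops when no two trees remain connectable,
i.e. one tree per connected component of the terminal-reachability
relation.  With k terminals the solution cost is within 2*ln(k) of the
optimal node-weighted Steiner tree.

Topology summaries (degree histogram with a log-log power-law exponent
fit, shortest-path-length histogram) are computed within the extracted
sub-network, and single-community Newman modularity of its node set is
computed against the full graph, with a permutation null over random
seed sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

__all__ = [
    "SteinerResult",
    "TopologySummary",
    "read_network",
    "klein_ravi",
    "steiner_cost",
    "topology",
    "modularity",
    "modularity_permutation",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class SteinerResult:
    """Extracted sub-network connecting a terminal (seed) gene set."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    terminals_included: frozenset[str]
    missing_terminals: frozenset[str]  # seeds absent from the input graph
    components: int
    linkers: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "linkers", frozenset(self.nodes - self.terminals_included)
        )


@dataclass(frozen=True)
class TopologySummary:
    degree_hist: dict[int, int]
    b: float  # power-law exponent in P(k) ~ k^(-b); NaN if < 2 distinct degrees
    path_hist: dict[int, int]
    unreachable_pairs: int
    Q: float  # single-community modularity of the node set in the full graph


def _canon_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected edge list (two-column TSV, or SIF ``a type b``).

    Duplicate and reversed-duplicate edges collapse to one; self-loops are
    dropped.  Raises on an empty file.
    """
    g = nx.Graph()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 3:  # SIF: source, interaction type, target
                u, _kind, v = fields
            elif len(fields) >= 2:
                u, v = fields[:2]
            else:
                raise ValueError(f"{path}: line {lineno}: expected an edge")
            if u == v:
                continue
            g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges found")
    return g


def _graph_arrays(
    g: nx.Graph, node_weight: Mapping[str, float] | None
) -> tuple[list[str], dict[str, int], np.ndarray, np.ndarray, np.ndarray]:
    """Lexicographic node order, index map, weight vector and edge arrays."""
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    w = np.ones(len(nodes))
    if node_weight:
        for n, wt in node_weight.items():
            if n in index:
                if wt <= 0:
                    raise ValueError(f"node weight for {n!r} must be positive")
                w[index[n]] = wt
    us, vs = [], []
    for a, b in g.edges():
        us.append(index[a])
        vs.append(index[b])
    return nodes, index, w, np.asarray(us, dtype=np.int64), np.asarray(vs, dtype=np.int64)


def klein_ravi(
    g: nx.Graph,
    terminals: Iterable[str],
    node_weight: Mapping[str, float] | None = None,
) -> SteinerResult:
    """Greedy spider-merge approximation of the node-weighted Steiner tree.

    Terminals absent from the graph are reported in
    ``missing_terminals`` and excluded (partial seed coverage is normal
    for pathway networks).  Deterministic for a given graph and terminal
    set: nodes are processed in lexicographic order, so the result does
    not depend on edge input order.
    """
    terminals = set(terminals)
    if not terminals:
        raise ValueError("terminal set is empty")
    missing = frozenset(t for t in terminals if t not in g)
    present = sorted(terminals - missing)
    if not present:
        raise ValueError("no terminal is present in the graph")

    nodes, index, w, us, vs = _graph_arrays(g, node_weight)
    n = len(nodes)
    term_idx = [index[t] for t in present]

    # state: one tree per terminal; trees hold node and edge index sets
    tree_nodes: list[set[int]] = [{t} for t in term_idx]
    tree_edges: list[set[tuple[int, int]]] = [set() for _ in term_idx]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[term_idx] = True

    while len(tree_nodes) > 1:
        # residual weights: nodes already bought by any tree are free
        w_res = np.where(in_tree, 0.0, w)
        # directed edge u->v costs w_res[v]; path cost from a source then
        # equals the residual weight of every node after the source
        data = np.concatenate([w_res[vs], w_res[us]])
        rows = np.concatenate([us, vs])
        cols = np.concatenate([vs, us])
        adj = csr_matrix((data, (rows, cols)), shape=(n, n))

        T = len(tree_nodes)
        dist = np.full((T, n), np.inf)
        preds = np.full((T, n), -9999, dtype=np.int32)
        for ti, tn in enumerate(tree_nodes):
            d, p, _ = _csgraph_dijkstra(
                adj,
                directed=True,
                indices=sorted(tn),
                min_only=True,
                return_predecessors=True,
            )
            dist[ti] = d
            preds[ti] = p
        # interior cost from tree ti to node v excludes v's own weight
        dv = np.maximum(dist - w_res[None, :], 0.0)
        dv_sorted = np.sort(dv, axis=0)
        order = np.argsort(dv, axis=0, kind="stable")
        cum = np.cumsum(dv_sorted, axis=0)
        sizes = np.arange(1, T + 1, dtype=float)[:, None]
        with np.errstate(invalid="ignore"):
            ratios = (w_res[None, :] + cum) / sizes
        ratios[0, :] = np.inf  # spiders must join at least two trees
        ratios[~np.isfinite(cum)] = np.inf

        best = np.min(ratios)
        if not np.isfinite(best):
            break  # remaining trees live in different components
        # deterministic tie-break: smallest node index (lexicographic
        # symbol), then largest merged-subset size
        cand_s, cand_v = np.where(ratios == best)
        pick = min(zip(cand_v, -cand_s))
        v = int(pick[0])
        s = int(-pick[1]) + 1  # number of trees merged

        merge_ids = sorted(int(order[j, v]) for j in range(s))
        new_nodes: set[int] = {v}
        new_edges: set[tuple[int, int]] = set()
        for ti in merge_ids:
            x = v
            while preds[ti, x] >= 0:
                px = int(preds[ti, x])
                new_edges.add((min(px, x), max(px, x)))
                new_nodes.add(px)
                x = px
        merged_nodes = set().union(*(tree_nodes[i] for i in merge_ids)) | new_nodes
        merged_edges = set().union(*(tree_edges[i] for i in merge_ids)) | new_edges
        tree_nodes = [tn for i, tn in enumerate(tree_nodes) if i not in merge_ids]
        tree_edges = [te for i, te in enumerate(tree_edges) if i not in merge_ids]
        tree_nodes.append(merged_nodes)
        tree_edges.append(merged_edges)
        in_tree[list(new_nodes)] = True

    all_nodes = set().union(*tree_nodes)
    all_edges = set().union(*tree_edges)
    return SteinerResult(
        nodes=frozenset(nodes[i] for i in all_nodes),
        edges=frozenset(_canon_edge(nodes[a], nodes[b]) for a, b in all_edges),
        terminals_included=frozenset(present),
        missing_terminals=missing,
        components=len(tree_nodes),
    )


def steiner_cost(
    result: SteinerResult, node_weight: Mapping[str, float] | None = None
) -> float:
    """Total weight of linker (non-terminal) nodes in the solution."""
    if node_weight is None:
        return float(len(result.linkers))
    return float(sum(node_weight.get(v, 1.0) for v in result.linkers))


def fit_power_law_exponent(degree_hist: Mapping[int, int]) -> float:
    """Exponent b of P(k) ~ k^(-b) by least squares on log10 count vs log10 k.

    Degrees with zero count are absent from the histogram by construction;
    degree 0 cannot enter a log-log fit and is ignored.  Returns NaN when
    fewer than two distinct positive degrees are observed.
    """
    ks = np.array([k for k, c in degree_hist.items() if k >= 1 and c >= 1], dtype=float)
    cs = np.array([degree_hist[int(k)] for k in ks], dtype=float)
    if len(ks) < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log10(ks), np.log10(cs), 1)
    return float(-slope)


def modularity(full: nx.Graph, node_set: Iterable[str]) -> float:
    """Single-community Newman modularity Q = e_S/m - (d_S/(2m))^2.

    e_S counts full-graph edges with both ends in the set, d_S is the total
    full-graph degree of the set, m the total edge count.  The empty set
    and the whole graph both give Q = 0.
    """
    nodes = set(node_set) & set(full.nodes())
    m = full.number_of_edges()
    if m == 0 or not nodes:
        return 0.0
    e_s = sum(1 for u, v in full.edges() if u in nodes and v in nodes)
    d_s = sum(d for _, d in full.degree(nodes))
    return e_s / m - (d_s / (2 * m)) ** 2


def topology(sub: SteinerResult, full: nx.Graph) -> TopologySummary:
    """Degree/path summaries of the sub-network plus its modularity in ``full``."""
    sg = nx.Graph()
    sg.add_nodes_from(sub.nodes)
    sg.add_edges_from(sub.edges)
    degree_hist: dict[int, int] = {}
    for _, d in sg.degree():
        degree_hist[d] = degree_hist.get(d, 0) + 1
    b = fit_power_law_exponent(degree_hist)

    path_hist: dict[int, int] = {}
    reachable_pairs = 0
    nodes_sorted = sorted(sg.nodes())
    pos = {v: i for i, v in enumerate(nodes_sorted)}
    for src in nodes_sorted:
        lengths = nx.single_source_shortest_path_length(sg, src)
        for dst, L in lengths.items():
            if pos[dst] > pos[src]:
                path_hist[L] = path_hist.get(L, 0) + 1
                reachable_pairs += 1
    n = sg.number_of_nodes()
    unreachable = n * (n - 1) // 2 - reachable_pairs
    return TopologySummary(
        degree_hist=dict(sorted(degree_hist.items())),
        b=b,
        path_hist=dict(sorted(path_hist.items())),
        unreachable_pairs=unreachable,
        Q=modularity(full, sub.nodes),
    )


def modularity_permutation(
    full: nx.Graph,
    seed_pool: Iterable[str],
    m: int,
    observed_q: float,
    n_permutations: int = 100,
    seed: int | np.random.Generator = 0,
    node_weight: Mapping[str, float] | None = None,
) -> tuple[list[float], float]:
    """Null distribution of Q for random seed sets, and the empirical p.

    Each permutation draws ``m`` genes without replacement from
    ``seed_pool``, extracts their Klein-Ravi sub-network and scores its
    node set's modularity against the full graph.  The add-one empirical
    p-value is (#{null Q >= observed} + 1) / (R + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pool = sorted(set(seed_pool) & set(full.nodes()))
    if m > len(pool):
        raise ValueError(f"m={m} exceeds seed pool size {len(pool)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null_q: list[float] = []
    for _ in range(n_permutations):
        random_seeds = rng.choice(pool, size=m, replace=False)
        sub = klein_ravi(full, random_seeds, node_weight=node_weight)
        null_q.append(modularity(full, sub.nodes))
    p = (sum(1 for q in null_q if q >= observed_q) + 1) / (n_permutations + 1)
    return null_q, p


def write_sif(result: SteinerResult, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(result.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_graphml(result: SteinerResult, path: str | Path) -> None:
    g = nx.Graph()
    for v in sorted(result.nodes):
        role = "terminal" if v in result.terminals_included else "linker"
        g.add_node(v, role=role)
    g.add_edges_from(sorted(result.edges))
    nx.write_graphml(g, path)


def nodes_frame(result: SteinerResult) -> pd.DataFrame:
    sg = nx.Graph()
    sg.add_nodes_from(result.nodes)
    sg.add_edges_from(result.edges)
    rows = [
        (
            v,
            "terminal" if v in result.terminals_included else "linker",
            sg.degree(v),
        )
        for v in sorted(result.nodes)
    ]
    return pd.DataFrame(rows, columns=["symbol", "role", "degree"])
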