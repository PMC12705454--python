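"""Markov clustering of the subtype graph and consensus-subtype mapping.

MCL alternates flow expansion (matrix powers) with inflation (element-wise
powers followed by column renormalization); the inflation factor controls
granularity. The selected partition maps multi-node clusters to consensus
transcriptomic subtypes (CTS), augments each CTS member set with subtypes
that overlap a cluster member significantly (so a 2-class system's subtype
can serve two CTSs), and defines core samples as those whose labels from
every system fall inside a single CTS member set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = [
    "MCLParams",
    "SilhouetteReport",
    "ConsensusMap",
    "SweepResult",
    "mcl_cluster",
    "inflation_sweep",
    "silhouette_widths",
    "map_clusters_to_cts",
    "identify_core_samples",
    "graph_adjacency",
]


@dataclass(frozen=True)
class MCLParams:
    expansion: int = 2
    inflation: float = 2.0
    self_loops: bool = True
    prune_threshold: float = 1e-5
    max_iter: int = 200
    tol: float = 1e-8
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    return m / col


def mcl_cluster(adjacency: np.ndarray, params: MCLParams = MCLParams()) -> np.ndarray:
    """Partition a non-negative symmetric weight matrix by Markov clustering.

    Returns integer cluster labels (0-based, ordered by smallest member
    index). Deterministic for a fixed input. Raises on non-convergence.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a < 0):
        raise ValueError("adjacency weights must be non-negative")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    m = a.copy()
    if params.self_loops:
        # self-loop weight = max incident weight (keeps weakly connected
        # nodes from being absorbed instantly); 1.0 for isolated nodes
        loops = m.max(axis=0)
        loops[loops == 0] = 1.0
        np.fill_diagonal(m, loops)
    m = _normalize_columns(m)

    residual = np.inf
    for _ in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = m**params.inflation
        m[m < params.prune_threshold] = 0.0
        m = _normalize_columns(m)
        residual = np.abs(m - prev).max()
        if residual < params.tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {params.max_iter} iterations "
            f"(residual {residual:.3g})"
        )

    return _read_clusters(m, thr=max(params.prune_threshold, params.tol))


def _read_clusters(m: np.ndarray, thr: float) -> np.ndarray:
    n = m.shape[0]
    attractors = np.where(np.diag(m) > thr)[0]
    if len(attractors) == 0:  # pathological; treat every node as its own
        return np.arange(n)
    # attractor systems: attractors mutually reachable share a cluster
    g = nx.Graph()
    g.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > thr or m[j, i] > thr):
                g.add_edge(i, j)
    systems = sorted(nx.connected_components(g), key=min)
    labels = np.full(n, -1, dtype=int)
    for cid, system in enumerate(systems):
        for i in system:
            labels[i] = cid
    # attach every remaining node to the system with the largest flow mass;
    # ties -> lowest cluster index
    for j in range(n):
        if labels[j] >= 0:
            continue
        mass = np.array([m[list(system), j].sum() for system in systems])
        if mass.max() <= 0:
            labels[j] = len(systems)  # unreachable: its own singleton
            systems.append({j})
        else:
            labels[j] = int(np.argmax(mass))
    # relabel by smallest member index for determinism
    order = {}
    for j in range(n):
        order.setdefault(labels[j], len(order))
    return np.array([order[c] for c in labels])


@dataclass
class SilhouetteReport:
    widths: np.ndarray  # per item, in [-1, 1]
    cluster_means: dict
    mean: float


def silhouette_widths(distance: np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Per-item silhouette widths s(i) = (b - a)/max(a, b) on a precomputed
    distance matrix; s(i) = 0 for singleton clusters. Errors on one cluster.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    widths = silhouette_samples(np.asarray(distance, float), labels,
                                metric="precomputed")
    means = {c: float(widths[labels == c].mean()) for c in np.unique(labels)}
    return SilhouetteReport(widths=widths, cluster_means=means,
                            mean=float(widths.mean()))


@dataclass
class SweepResult:
    table: pd.DataFrame  # inflation, n_clusters, mean_silhouette, stable
    selected_inflation: float
    assignments: dict  # inflation -> labels


def inflation_sweep(
    adjacency: np.ndarray,
    item_distance: np.ndarray | None = None,
    inflations: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7),
    n_repeats: int = 10,
    params: MCLParams = MCLParams(),
) -> SweepResult:
    """Run MCL over an inflation grid and select by mean silhouette.

    ``item_distance`` is the pairwise distance between the clustered items
    (default: 1 - normalized adjacency weight). Selection maximizes the mean
    silhouette width; ties break toward the smaller inflation. Repeat
    stability (identical partitions across ``n_repeats`` runs) is recorded.
    """
    if min(inflations) < 1 or max(inflations) > 7:
        raise ValueError("inflation grid must lie within [1, 7]")
    a = np.asarray(adjacency, dtype=float)
    if item_distance is None:
        wmax = a.max() if a.max() > 0 else 1.0
        item_distance = 1.0 - a / wmax
        np.fill_diagonal(item_distance, 0.0)

    rows, assignments = [], {}
    for infl in inflations:
        p = MCLParams(
            expansion=params.expansion, inflation=float(infl),
            self_loops=params.self_loops,
            prune_threshold=params.prune_threshold,
            max_iter=params.max_iter, tol=params.tol, n_repeats=n_repeats,
        )
        runs = [mcl_cluster(a, p) for _ in range(max(n_repeats, 1))]
        labels = runs[0]
        stable = all(np.array_equal(labels, r) for r in runs[1:])
        n_clusters = len(np.unique(labels))
        if n_clusters >= 2:
            sil = silhouette_widths(item_distance, labels).mean
        else:
            sil = float("nan")
        rows.append((float(infl), n_clusters, sil, stable))
        assignments[float(infl)] = labels
    table = pd.DataFrame(
        rows, columns=["inflation", "n_clusters", "mean_silhouette", "stable"]
    )
    if table["n_clusters"].max() < 2:
        raise ValueError("no structure: every inflation yields a single cluster")
    valid = table.dropna(subset=["mean_silhouette"])
    best = valid["mean_silhouette"].max()
    selected = float(valid.loc[valid["mean_silhouette"] >= best - 1e-12,
                               "inflation"].min())
    return SweepResult(table=table, selected_inflation=selected,
                       assignments=assignments)


@dataclass
class ConsensusMap:
    """Mapping from graph nodes to consensus subtypes (CTS ids from 1)."""

    cluster_of_node: dict  # node -> MCL cluster id
    cts_of_cluster: dict  # multi-node cluster id -> CTS id
    members: dict  # CTS id -> set of (system, subtype) nodes
    unclustered: list = field(default_factory=list)


def graph_adjacency(graph: nx.Graph, weight: str = "jaccard"):
    """Node list and dense weighted adjacency of a subtype graph."""
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=weight)
    return nodes, a


def map_clusters_to_cts(
    graph: nx.Graph, clusters: dict, alpha: float = 0.05,
    include_unclustered: bool = False,
) -> ConsensusMap:
    """Turn an MCL partition of the subtype graph into a consensus map.

    Each multi-node cluster becomes one CTS (ids contiguous from 1, ordered
    by cluster id). A cluster lacking any subtype from some classification
    system is completed by adding that system's subtype(s) whose BH-adjusted
    hypergeometric q is below ``alpha`` against a member of the cluster --
    this is how a 2-class system's subtype serves two CTSs. Singleton
    (unclustered) nodes are listed separately; ``include_unclustered``
    additionally lets them join a CTS through the same overlap rule.
    """
    by_cluster: dict[int, list] = {}
    for node, cid in clusters.items():
        by_cluster.setdefault(cid, []).append(node)
    multi = {cid: sorted(nodes) for cid, nodes in by_cluster.items()
             if len(nodes) > 1}
    if not multi:
        raise ValueError("no multi-node cluster: nothing to map to a CTS")
    cts_of_cluster = {cid: i + 1 for i, cid in enumerate(sorted(multi))}
    members = {cts: set(multi[cid]) for cid, cts in cts_of_cluster.items()}
    unclustered = sorted(n for n, cid in clusters.items() if cid not in multi)

    candidates = sorted(clusters) if include_unclustered else sorted(
        n for n, c in clusters.items() if c in multi
    )
    systems = {node[0] for node in clusters}
    for cts in sorted(members):
        base = frozenset(members[cts])
        covered = {node[0] for node in base}
        for system in sorted(systems - covered):
            for node in candidates:
                if node[0] != system or node in base:
                    continue
                qs = [
                    graph.edges[node, member]["q_hyper"]
                    for member in base
                    if graph.has_edge(node, member)
                ]
                if qs and min(qs) < alpha:
                    members[cts].add(node)
    return ConsensusMap(
        cluster_of_node=dict(clusters),
        cts_of_cluster=cts_of_cluster,
        members={cts: set(m) for cts, m in members.items()},
        unclustered=unclustered,
    )


def identify_core_samples(
    labels: pd.DataFrame, consensus: ConsensusMap
) -> dict[int, list]:
    """Core samples per CTS: every system's label lies in the CTS member set.

    A system with no member in a CTS's set is ignored for that CTS (with a
    warning). Samples qualifying for more than one CTS are dropped so that
    core sets stay disjoint.
    """
    systems = list(labels.columns)
    core: dict[int, set] = {cts: set() for cts in consensus.members}
    member_labels = {
        cts: {(sys, sub) for sys, sub in mem}
        for cts, mem in consensus.members.items()
    }
    for cts, mem in member_labels.items():
        missing = [s for s in systems if not any(sys == s for sys, _ in mem)]
        if missing:
            warnings.warn(
                f"CTS{cts} has no member from system(s) {missing}; ignored"
            )
    assigned: dict = {}
    for sample, row in labels.iterrows():
        hits = []
        for cts, mem in member_labels.items():
            ok = True
            for system in systems:
                if not any(sys == system for sys, _ in mem):
                    continue
                if (system, str(row[system])) not in mem:
                    ok = False
                    break
            if ok:
                hits.append(cts)
        if len(hits) == 1:
            assigned[sample] = hits[0]
    for sample, cts in assigned.items():
        core[cts].add(sample)
    return {cts: sorted(s) for cts, s in core.items()}
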