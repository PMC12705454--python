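"""Cross-classifier subtype overlap network.

Each subtype of each classification system becomes a node carrying its
member-sample set. Every cross-system node pair is scored with the Jaccard
index, a permutation p-value for the Jaccard statistic, a one-sided
hypergeometric overlap p-value on the shared sample universe, and a
Benjamini-Hochberg q-value computed over the full cross-system edge family.
Edges are retained regardless of significance; downstream consensus mapping
uses the q-values as attributes.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "jaccard_index",
    "jaccard_bootstrap_p",
    "hypergeom_overlap_p",
    "bh_adjust",
    "build_network",
]


def jaccard_index(a: set, b: set) -> float:
    """|A n B| / |A u B|; error when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined: both sets empty")
    return len(a & b) / len(union)


def jaccard_bootstrap_p(
    labels_a: pd.Series,
    labels_b: pd.Series,
    subtype_a,
    subtype_b,
    n_boot: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the Jaccard index between two subtypes.

    One system's label vector is permuted over samples ``n_boot`` times;
    p = (1 + #{permuted J >= observed J}) / (n_boot + 1) (add-one estimator,
    never exactly zero).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels_a, labels_b = labels_a.align(labels_b, join="inner")
    if labels_a.nunique() < 2 or labels_b.nunique() < 2:
        warnings.warn("degenerate single-label system; permutation p = 1")
        return 1.0
    in_a = (labels_a == subtype_a).to_numpy()
    in_b = (labels_b == subtype_b).to_numpy()
    observed = _jaccard_bool(in_a, in_b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(in_b)
        if _jaccard_bool(in_a, perm) >= observed:
            count += 1
    return (1 + count) / (n_boot + 1)


def _jaccard_bool(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def hypergeom_overlap_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided overrepresentation p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, same order as the input."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    labels: pd.DataFrame,
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    prune_alpha: float | None = None,
) -> nx.Graph:
    """Build the weighted subtype graph from a samples x systems label table.

    Nodes are (system, subtype) pairs with their member-sample sets; edges
    connect subtypes of different systems and carry ``jaccard``, ``p_boot``
    (NaN when ``n_boot`` is 0), ``p_hyper`` and the BH-adjusted ``q_hyper``
    over the full cross-system family. ``prune_alpha`` optionally drops
    edges with q above the threshold.
    """
    if labels.shape[1] < 2:
        raise ValueError("need at least 2 classification systems")
    complete = labels.dropna()
    if len(complete) < len(labels):
        warnings.warn(
            f"restricting to the {len(complete)} samples labeled by all systems"
        )
    if len(complete) < 2:
        raise ValueError("fewer than 2 samples shared across systems")
    labels = complete
    universe = labels.index
    n_universe = len(universe)

    graph = nx.Graph(n_samples=n_universe)
    members: dict[tuple[str, str], set] = {}
    for system in labels.columns:
        for subtype in sorted(labels[system].unique()):
            node = (system, str(subtype))
            members[node] = set(universe[labels[system] == subtype])
            graph.add_node(node, system=system, subtype=str(subtype),
                           size=len(members[node]))

    rng = np.random.default_rng(seed)
    edges = []
    for sys_a, sys_b in combinations(labels.columns, 2):
        for node_a in sorted(n for n in members if n[0] == sys_a):
            for node_b in sorted(n for n in members if n[0] == sys_b):
                a, b = members[node_a], members[node_b]
                jac = jaccard_index(a, b)
                p_hyp = hypergeom_overlap_p(
                    len(a & b), len(a), len(b), n_universe
                )
                if n_boot:
                    p_boot = jaccard_bootstrap_p(
                        labels[sys_a], labels[sys_b],
                        node_a[1], node_b[1],
                        n_boot=n_boot,
                        seed=int(rng.integers(2**31)),
                    )
                else:
                    p_boot = float("nan")
                edges.append((node_a, node_b, jac, p_boot, p_hyp))

    q_vals = bh_adjust([e[4] for e in edges])
    for (node_a, node_b, jac, p_boot, p_hyp), q in zip(edges, q_vals):
        if prune_alpha is not None and q >= prune_alpha:
            continue
        graph.add_edge(
            node_a, node_b,
            jaccard=jac, p_boot=p_boot, p_hyper=p_hyp, q_hyper=float(q),
            significant=bool(q < alpha),
        )
    for node, mem in members.items():
        graph.nodes[node]["members"] = frozenset(mem)
    return graph
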