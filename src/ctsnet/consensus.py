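"""Resampling-based consensus clustering for de novo subtype discovery.

Repeatedly subsample samples and genes, hierarchically cluster each draw at
every k in the range, and tally how often each sample pair lands in the same
cluster relative to how often it was co-sampled. The per-k consensus
matrices yield CDF/area statistics, silhouettes on the 1-consensus distance,
and cophenetic correlations; the optimal k maximizes the cophenetic
correlation (delta-area and silhouette reported as secondary evidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .mcl import silhouette_widths

__all__ = [
    "ConsensusConfig",
    "ConsensusResult",
    "one_minus_pearson",
    "consensus_cluster",
    "cophenetic_correlation",
    "concordance_table",
]


@dataclass(frozen=True)
class ConsensusConfig:
    p_item: float = 0.9
    p_gene: float = 0.9
    n_reps: int = 1000
    k_range: tuple[int, ...] = tuple(range(2, 11))
    linkage_method: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_item <= 1) or not (0 < self.p_gene <= 1):
            raise ValueError("resampling fractions must lie in (0, 1]")
        if min(self.k_range) < 2:
            raise ValueError("k_range must start at 2 or above")


def one_minus_pearson(expr: pd.DataFrame) -> np.ndarray:
    """Pairwise sample distance 1 - r(x_i, x_j) in [0, 2] (genes x samples in)."""
    x = expr.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = list(expr.columns[sd == 0])
        raise ValueError(f"zero-variance sample(s): {bad[:5]}")
    d = 1.0 - np.corrcoef(x.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ConsensusResult:
    config: ConsensusConfig
    consensus: dict  # k -> samples x samples consensus matrix (DataFrame)
    cdf: dict  # k -> (grid, cdf values)
    area: dict  # k -> area under consensus CDF
    delta_area: dict  # k -> relative increase in area
    silhouette: dict  # k -> mean silhouette on 1-consensus distance
    cophenetic: dict  # k -> cophenetic correlation on 1-consensus distance
    labels: dict  # k -> per-sample labels (Series, clusters 1..k)
    selected_k: int


def consensus_cluster(expr: pd.DataFrame, config: ConsensusConfig) -> ConsensusResult:
    """Run resampled hierarchical consensus clustering over ``config.k_range``.

    Item/gene subsampling is without replacement. Deterministic given
    ``config.seed``.
    """
    samples = list(expr.columns)
    n = len(samples)
    if n < max(config.k_range) * 2:
        raise ValueError(
            f"need at least {max(config.k_range) * 2} samples for "
            f"k up to {max(config.k_range)}"
        )
    g = expr.shape[0]
    rng = np.random.default_rng(config.seed)
    n_items = max(2, int(round(config.p_item * n)))
    n_genes = max(2, int(round(config.p_gene * g)))
    x = expr.to_numpy(dtype=float)

    ks = sorted(config.k_range)
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(config.n_reps):
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        genes = rng.choice(g, size=n_genes, replace=False)
        sub = x[np.ix_(genes, items)]
        sd = sub.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        items = items[ok]
        sub = sub[:, ok]
        d = 1.0 - np.corrcoef(sub.T)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(np.clip(d, 0.0, 2.0), checks=False),
                    method=config.linkage_method)
        co_sampled[np.ix_(items, items)] += 1.0
        for k in ks:
            lab = fcluster(z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(items, items)] += same

    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = {
            k: np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
            for k in ks
        }
    for k in ks:
        np.fill_diagonal(consensus[k], 1.0)

    cdf, area, silhouette, cophenetic, labels = {}, {}, {}, {}, {}
    for k in ks:
        m = consensus[k]
        vals = np.sort(m[np.triu_indices(n, k=1)])
        grid = np.concatenate([[0.0], vals, [1.0]])
        cdf_vals = np.searchsorted(vals, grid, side="right") / len(vals)
        cdf[k] = (grid, cdf_vals)
        area[k] = float(np.sum(np.diff(grid) * cdf_vals[:-1]))
        dist = 1.0 - m
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False),
                    method=config.linkage_method)
        lab = fcluster(z, t=k, criterion="maxclust")
        labels[k] = pd.Series(lab, index=samples, name=f"k{k}")
        silhouette[k] = (
            silhouette_widths(dist, lab).mean if len(np.unique(lab)) > 1
            else float("nan")
        )
        cophenetic[k] = cophenetic_correlation(dist, z)
        consensus[k] = pd.DataFrame(m, index=samples, columns=samples)

    delta_area = {}
    prev = None
    for k in ks:
        delta_area[k] = (
            area[k] if prev is None else (area[k] - area[prev]) / area[prev]
        )
        prev = k
    selected = _select_k(ks, cophenetic, delta_area)
    return ConsensusResult(
        config=config, consensus=consensus, cdf=cdf, area=area,
        delta_area=delta_area, silhouette=silhouette, cophenetic=cophenetic,
        labels=labels, selected_k=int(selected),
    )


def _select_k(ks, cophenetic, delta_area, saturation_tol=1e-3,
              elbow_threshold=0.1):
    """Optimal k: maximal cophenetic correlation, with a saturation fallback.

    When the consensus matrices are nearly binary, every k up to the true
    cluster count yields a (numerically) perfect ultrametric and the
    cophenetic criterion cannot discriminate; among such saturated k the
    CDF delta-area elbow decides: the largest candidate whose relative area
    gain still exceeds ``elbow_threshold``.
    """
    best = max(cophenetic[k] for k in ks)
    candidates = [k for k in ks if cophenetic[k] >= best - saturation_tol]
    if len(candidates) == 1:
        return candidates[0]
    elbow = [k for k in candidates if delta_area[k] >= elbow_threshold]
    if elbow:
        return max(elbow)
    return min(candidates)


def cophenetic_correlation(distance: np.ndarray, dendrogram: np.ndarray) -> float:
    """Pearson r between original and dendrogram-implied (cophenetic) distances."""
    d = np.asarray(distance, dtype=float)
    if d.ndim == 2:
        if d.shape[0] < 3:
            raise ValueError("need at least 3 items")
        d = squareform(d, checks=False)
    coph = cophenet(dendrogram)
    if np.std(d) == 0 or np.std(coph) == 0:
        return 1.0 if np.allclose(d, coph) else 0.0
    return float(np.corrcoef(d, coph)[0, 1])


def concordance_table(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Row-normalized cross-tabulation (%): share of each a-class per b-class."""
    labels_a, labels_b = labels_a.align(labels_b, join="inner")
    tab = pd.crosstab(labels_a, labels_b)
    totals = tab.sum(axis=1)
    if (totals == 0).any():
        import warnings

        warnings.warn("empty class row(s) in concordance table")
    pct = tab.div(totals.replace(0, np.nan), axis=0) * 100.0
    return pct.fillna(0.0)
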