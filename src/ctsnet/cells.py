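"""Rank-based per-cell gene-set activity scoring (AUCell-style).

Each cell's genes are ranked by decreasing expression (ties, including the
zero block, broken uniformly at random with a recorded seed); a gene set's
score is the area under its recovery curve within the top fraction of the
ranking, normalized by the maximal achievable area. Scores are invariant to
monotone transformations of expression within a cell.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = ["CellScores", "rank_genes_per_cell", "aucell_score", "score_matrix"]


def _dense(counts) -> tuple[np.ndarray, list, list]:
    if isinstance(counts, AnnData):
        x = counts.X
        cells = list(counts.obs_names)
        genes = list(counts.var_names)
    else:
        x = counts.to_numpy() if isinstance(counts, pd.DataFrame) else counts
        cells = list(counts.index) if isinstance(counts, pd.DataFrame) else [
            f"cell{i}" for i in range(x.shape[0])
        ]
        genes = list(counts.columns) if isinstance(counts, pd.DataFrame) else [
            f"g{i}" for i in range(x.shape[1])
        ]
    if sparse.issparse(x):
        x = x.toarray()
    return np.asarray(x, dtype=float), cells, genes


def rank_genes_per_cell(counts, seed: int = 0) -> pd.DataFrame:
    """Per-cell gene rankings: rank 1 = highest expression in that cell.

    Ties are broken uniformly at random (seeded). Cells with no expressed
    gene are an error.
    """
    x, cells, genes = _dense(counts)
    zero_cells = [c for c, row in zip(cells, x) if not np.any(row > 0)]
    if zero_cells:
        raise ValueError(f"all-zero cell(s): {zero_cells[:5]}")
    # tie-break keys are seeded per cell identity, so reordering cells
    # permutes the resulting rankings identically
    tiebreak = np.empty_like(x)
    for i, cell in enumerate(cells):
        key = zlib.crc32(str(cell).encode())
        tiebreak[i] = np.random.default_rng([seed, key]).random(x.shape[1])
    # sort each cell's genes by (-expression, random key): highest first
    order = np.lexsort((tiebreak, -x))  # last key is primary
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, x.shape[1] + 1)[None, :]
    return pd.DataFrame(ranks, index=cells, columns=genes)


def aucell_score(
    ranking: pd.Series | np.ndarray,
    gene_set: list[str] | np.ndarray,
    top_frac: float = 0.05,
    gene_ids: list[str] | None = None,
) -> float:
    """Normalized recovery-curve AUC of one gene set in one cell's ranking.

    The step recovery curve counts set genes found at ranks 1..W where
    W = ceil(top_frac * G); the integral is divided by its maximum (all set
    genes packed at the top). Returns a value in [0, 1].
    """
    if isinstance(ranking, pd.Series):
        ranks_all = ranking
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required with an array ranking")
        ranks_all = pd.Series(np.asarray(ranking), index=gene_ids)
    n_genes = len(ranks_all)
    window = math.ceil(top_frac * n_genes)
    if window < 1:
        raise ValueError("top window smaller than 1 gene")
    in_set = ranks_all.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("gene set has no gene in the ranking universe")
    set_ranks = np.sort(ranks_all.to_numpy()[in_set])
    return _recovery_auc(set_ranks, window)


def _recovery_auc(set_ranks: np.ndarray, window: int) -> float:
    inside = set_ranks[set_ranks <= window]
    # integral of the step curve over x = 1..W equals sum over recovered
    # genes of (W - rank + 1)
    auc = float(np.sum(window - inside + 1))
    k = min(len(set_ranks), window)
    max_auc = float(np.sum(window - np.arange(1, k + 1) + 1))
    return auc / max_auc if max_auc > 0 else 0.0


@dataclass
class CellScores:
    scores: pd.DataFrame  # cells x sets, in [0, 1]
    by_type: pd.DataFrame  # cell types x sets, mean scores
    top_frac: float


def score_matrix(
    counts,
    sets: dict[str, list[str]],
    annotations: pd.Series,
    top_frac: float = 0.05,
    seed: int = 0,
) -> CellScores:
    """Score every cell against every gene set; aggregate means per cell type.

    Sets with no gene in the universe score NaN (with a warning).
    """
    ranks = rank_genes_per_cell(counts, seed=seed)
    annotations = annotations.reindex(ranks.index)
    if annotations.isna().any():
        raise ValueError("annotations must cover all cells")
    n_genes = ranks.shape[1]
    window = math.ceil(top_frac * n_genes)
    if window < 1:
        raise ValueError("top window smaller than 1 gene")
    universe = ranks.columns
    rank_mat = ranks.to_numpy()
    out = {}
    for name, genes in sets.items():
        mask = universe.isin(set(genes))
        if not mask.any():
            warnings.warn(f"gene set {name!r} has no gene in the universe")
            out[name] = np.full(rank_mat.shape[0], np.nan)
            continue
        sub = rank_mat[:, mask]
        inside = np.where(sub <= window, window - sub + 1, 0)
        k = min(mask.sum(), window)
        max_auc = np.sum(window - np.arange(1, k + 1) + 1)
        out[name] = inside.sum(axis=1) / max_auc
    scores = pd.DataFrame(out, index=ranks.index)
    by_type = scores.groupby(annotations, observed=True).mean()
    return CellScores(scores=scores, by_type=by_type, top_frac=top_frac)
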