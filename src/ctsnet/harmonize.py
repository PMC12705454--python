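"""Transcript collapsing, empirical-Bayes batch adjustment and PCA overview.

Multi-platform expression matrices are collapsed to unique genes (mean of a
gene's transcripts) and then adjusted for non-experimental batch effects
with the parametric empirical-Bayes location/scale model (ComBat): per-gene
standardization, per-batch additive (gamma) and multiplicative (delta)
estimates shrunk toward method-of-moments priors, then back-transformation.
No covariates other than batch enter the design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["BatchAdjustment", "collapse_transcripts", "combat_adjust", "pca_overview"]


def collapse_transcripts(
    transcript_matrix: pd.DataFrame, transcript_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a transcripts x samples matrix to unique genes.

    Each gene's value is the arithmetic mean of its transcripts' values per
    sample. Gene order is lexicographic. Raises if any transcript lacks a
    mapping.
    """
    unmapped = [t for t in transcript_matrix.index if t not in transcript_to_gene]
    if unmapped:
        raise KeyError(f"unmapped transcript id(s): {unmapped}")
    genes = transcript_matrix.index.map(transcript_to_gene.__getitem__)
    collapsed = transcript_matrix.groupby(genes, sort=True).mean()
    collapsed.index.name = "gene"
    return collapsed


@dataclass
class BatchAdjustment:
    """Fitted batch-adjustment parameters (one entry per batch and gene)."""

    grand_mean: pd.Series  # alpha_g
    pooled_var: pd.Series
    gamma_star: pd.DataFrame  # batches x genes, EB-shrunk additive effects
    delta_star: pd.DataFrame  # batches x genes, EB-shrunk multiplicative effects
    gamma_bar: pd.Series  # per-batch prior mean of gamma
    tau_sq: pd.Series  # per-batch prior variance of gamma
    a_prior: pd.Series  # per-batch inverse-gamma shape for delta^2
    b_prior: pd.Series  # per-batch inverse-gamma scale for delta^2
    dropped_genes: list[str]


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(z, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative EB solution for one batch (standardized data z: genes x n_b)."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum_sq, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() else 0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    expr: pd.DataFrame, batch: pd.Series, parametric: bool = True
) -> tuple[pd.DataFrame, BatchAdjustment]:
    """Remove batch effects with the parametric EB location/scale model.

    Returns the adjusted matrix (same shape, minus genes with zero pooled
    variance, which are dropped with a logged count) and the fitted
    adjustment. A batch with a single sample is an error. With a single
    batch the input is returned unchanged (identity adjustment).
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB mode is implemented")
    batch = batch.reindex(expr.columns)
    if batch.isna().any():
        raise ValueError("every sample needs a batch id")
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    singletons = [b for b in levels if counts[b] < 2]
    if singletons:
        raise ValueError(f"batch(es) with a single sample: {singletons}")

    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_b = np.array([masks[b].sum() for b in levels], dtype=float)

    batch_means = np.stack([x[:, masks[b]].mean(axis=1) for b in levels])  # B x G
    grand_mean = (n_b[:, None] / n * batch_means).sum(axis=0)
    fitted = np.empty_like(x)
    for i, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[i][:, None]
    pooled_var = ((x - fitted) ** 2).mean(axis=1)

    keep = pooled_var > 0
    n_dropped = int((~keep).sum())
    dropped = list(expr.index[~keep])
    if n_dropped:
        logger.warning("dropping %d gene(s) with zero pooled variance", n_dropped)
    x = x[keep]
    grand_mean_k = grand_mean[keep]
    pooled_var_k = pooled_var[keep]
    gene_index = expr.index[keep]

    if len(levels) == 1:
        adj = pd.DataFrame(x, index=gene_index, columns=expr.columns)
        ident = BatchAdjustment(
            grand_mean=pd.Series(grand_mean_k, index=gene_index),
            pooled_var=pd.Series(pooled_var_k, index=gene_index),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=gene_index),
            delta_star=pd.DataFrame(1.0, index=levels, columns=gene_index),
            gamma_bar=pd.Series(0.0, index=levels),
            tau_sq=pd.Series(0.0, index=levels),
            a_prior=pd.Series(np.nan, index=levels),
            b_prior=pd.Series(np.nan, index=levels),
            dropped_genes=dropped,
        )
        return adj, ident

    sd = np.sqrt(pooled_var_k)
    z = (x - grand_mean_k[:, None]) / sd[:, None]

    gamma_hat = np.stack([z[:, masks[b]].mean(axis=1) for b in levels])
    delta_hat = np.stack([z[:, masks[b]].var(axis=1, ddof=1) for b in levels])

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    v, s2 = delta_hat.mean(axis=1), delta_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + v**2) / s2
    b_prior = (v * s2 + v**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(levels):
        zb = z[:, masks[b]]
        # zero within-batch variance: shrinkage keeps delta* positive via the
        # prior scale; the additive term still centers the batch
        g, d = _it_sol(
            zb, gamma_hat[i], np.maximum(delta_hat[i], 1e-12), gamma_bar[i],
            max(tau_sq[i], 1e-12), a_prior[i], b_prior[i],
        )
        gamma_star[i], delta_star[i] = g, d

    adj = np.empty_like(z)
    for i, b in enumerate(levels):
        adj[:, masks[b]] = (z[:, masks[b]] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    adj = adj * sd[:, None] + grand_mean_k[:, None]

    fit = BatchAdjustment(
        grand_mean=pd.Series(grand_mean_k, index=gene_index),
        pooled_var=pd.Series(pooled_var_k, index=gene_index),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=gene_index),
        delta_star=pd.DataFrame(delta_star, index=levels, columns=gene_index),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau_sq=pd.Series(tau_sq, index=levels),
        a_prior=pd.Series(a_prior, index=levels),
        b_prior=pd.Series(b_prior, index=levels),
        dropped_genes=dropped,
    )
    return pd.DataFrame(adj, index=gene_index, columns=expr.columns), fit


def pca_overview(
    expr: pd.DataFrame, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of gene-centered data; samples are observations.

    Returns per-sample coordinates and explained-variance fractions
    (non-increasing, summing to at most 1).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    n_components = min(n_components, min(expr.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(expr.to_numpy().T)
    coords_df = pd.DataFrame(
        coords,
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coords_df, pca.explained_variance_ratio_
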