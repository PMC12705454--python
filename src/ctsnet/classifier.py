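"""Gene-panel derivation and random-forest consensus-subtype classification.

Genes are ranked by one-versus-all Kruskal-Wallis significance on core
samples; tenfold cross-validation over a grid of panel sizes (with the
ranking recomputed inside every training fold to avoid selection leakage)
picks the smallest panel with a CV misclassification rate below 5%; the
final 500-tree random forest reports its out-of-bag error and per-sample
posterior probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GeneRanking",
    "CVReport",
    "CTSModel",
    "kruskal_wallis",
    "rank_genes",
    "cv_panel_selection",
    "fit_final",
    "predict",
    "brier_score",
    "one_vs_all_auc",
    "DEFAULT_PANEL_GRID",
]

DEFAULT_PANEL_GRID: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20,
                                       22, 24, 26, 28, 30, 40, 50)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) and chi-squared p."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError:  # all values identical: no separation
        return 0.0, 1.0
    return float(h), float(p)


def _kw_one_vs_all(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-vs-all Kruskal-Wallis over genes (rows of ``values``).

    ``mask`` flags the "one" group's samples. Tie-corrected; degenerate
    (constant) genes get H=0, p=1.
    """
    g, n = values.shape
    ranks = stats.rankdata(values, axis=1)
    n1 = int(mask.sum())
    n0 = n - n1
    r1 = ranks[:, mask].sum(axis=1)
    r0 = ranks.sum(axis=1) - r1
    h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r0**2 / n0) - 3.0 * (n + 1)
    # tie correction per gene
    tie = np.ones(g)
    for i in range(g):
        _, counts = np.unique(values[i], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie[i] = 1.0 - (t**3 - t).sum() / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(tie > 0, h / tie, 0.0)
    h = np.clip(h, 0.0, None)
    p = np.where(tie > 0, stats.chi2.sf(h, df=1), 1.0)
    return h, p


@dataclass
class GeneRanking:
    """Ordered gene ranking with per-CTS one-vs-all KW statistics."""

    table: pd.DataFrame  # indexed by gene, ordered; H_/p_ columns per CTS

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def rank_genes(
    expr: pd.DataFrame, cts_labels: pd.Series, top_n: int = 5000
) -> GeneRanking:
    """Rank genes by one-vs-all KW significance across consensus subtypes.

    Ordering: smallest min p across subtypes first, ties broken by largest
    max H, then lexicographic gene id. Truncated at ``top_n``. Constant
    genes sort last.
    """
    cts_labels = cts_labels.reindex(expr.columns)
    if cts_labels.isna().any():
        raise ValueError("labels must cover every sample")
    classes = sorted(cts_labels.unique())
    if len(classes) < 2:
        raise ValueError("labels must cover at least 2 subtypes")
    values = expr.to_numpy(dtype=float)
    out = {}
    for c in classes:
        mask = (cts_labels == c).to_numpy()
        h, p = _kw_one_vs_all(values, mask)
        out[f"H_{c}"] = h
        out[f"p_{c}"] = p
    table = pd.DataFrame(out, index=expr.index)
    h_cols = [f"H_{c}" for c in classes]
    p_cols = [f"p_{c}" for c in classes]
    table["min_p"] = table[p_cols].min(axis=1)
    table["max_H"] = table[h_cols].max(axis=1)
    table = table.assign(_gene=table.index).sort_values(
        by=["min_p", "max_H", "_gene"], ascending=[True, False, True]
    ).drop(columns="_gene")
    return GeneRanking(table=table.head(top_n))


@dataclass
class CVReport:
    """Tenfold cross-validation curves over the panel-size grid."""

    grid: tuple[int, ...]
    misclassification: dict  # size -> CV error rate
    brier: dict  # size -> multiclass Brier score
    avg_correct_prob: dict  # size -> mean posterior of the true class
    selected_size: int
    threshold: float


def cv_panel_selection(
    expr: pd.DataFrame,
    labels: pd.Series,
    grid: tuple[int, ...] = DEFAULT_PANEL_GRID,
    folds: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    error_threshold: float = 0.05,
) -> CVReport:
    """Select the panel size by stratified tenfold cross-validation.

    Gene ranking is recomputed inside each training fold; the selected size
    is the smallest with CV misclassification below ``error_threshold``
    (best size with a warning when none qualifies).
    """
    labels = labels.reindex(expr.columns)
    counts = labels.value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"every class needs >= {folds} members, got {counts.to_dict()}"
        )
    classes = np.array(sorted(labels.unique()))
    y = labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = expr.shape[1]
    sizes = sorted(grid)
    errors = {s: 0.0 for s in sizes}
    briers = {s: 0.0 for s in sizes}
    probs = {s: 0.0 for s in sizes}
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        train_cols = expr.columns[train_idx]
        test_cols = expr.columns[test_idx]
        ranking = rank_genes(expr[train_cols], labels[train_cols],
                             top_n=max(sizes))
        for size in sizes:
            panel = ranking.genes[:size]
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            )
            rf.fit(expr.loc[panel, train_cols].T, y[train_idx])
            post = rf.predict_proba(expr.loc[panel, test_cols].T)
            pred = rf.classes_[np.argmax(post, axis=1)]
            truth = y[test_idx]
            errors[size] += np.sum(pred != truth)
            onehot = (truth[:, None] == rf.classes_[None, :]).astype(float)
            briers[size] += np.sum(((post - onehot) ** 2).sum(axis=1))
            probs[size] += np.sum(post[onehot.astype(bool)])
    for size in sizes:
        errors[size] /= n
        briers[size] /= n
        probs[size] /= n
    qualifying = [s for s in sizes if errors[s] < error_threshold]
    if qualifying:
        selected = qualifying[0]
    else:
        selected = min(sizes, key=lambda s: (errors[s], s))
        warnings.warn(
            f"no panel size reached CV error < {error_threshold:.0%}; "
            f"returning best size {selected} (error {errors[selected]:.3f})"
        )
    return CVReport(
        grid=tuple(sizes), misclassification=errors, brier=briers,
        avg_correct_prob=probs, selected_size=selected,
        threshold=error_threshold,
    )


@dataclass
class CTSModel:
    """Trained consensus-subtype classifier."""

    panel: list[str]
    forest: RandomForestClassifier
    classes: list
    oob_error: float
    oob_votes: np.ndarray  # training samples x classes
    n_trees: int
    seed: int
    training_samples: list[str]

    def to_metadata(self) -> dict:
        return {
            "panel": list(self.panel),
            "classes": [str(c) for c in self.classes],
            "oob_error": self.oob_error,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "n_training_samples": len(self.training_samples),
        }


def fit_final(
    expr: pd.DataFrame,
    labels: pd.Series,
    panel: list[str],
    n_trees: int = 500,
    seed: int = 0,
) -> CTSModel:
    """Fit the final random forest on the panel; OOB error from out-of-bag votes."""
    if not panel:
        raise ValueError("panel must be non-empty")
    missing = [g for g in panel if g not in expr.index]
    if missing:
        raise KeyError(f"panel genes missing from expression: {missing}")
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every training sample")
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse OOB coverage at tiny n
        rf.fit(expr.loc[panel].T, labels.to_numpy())
    return CTSModel(
        panel=list(panel),
        forest=rf,
        classes=list(rf.classes_),
        oob_error=float(1.0 - rf.oob_score_),
        oob_votes=rf.oob_decision_function_,
        n_trees=n_trees,
        seed=seed,
        training_samples=list(expr.columns),
    )


def predict(model: CTSModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample subtype call and posterior probabilities.

    Rows sum to 1; the call is the argmax (ties resolve to the lowest
    subtype index). The ``high_confidence`` column flags max posterior > 0.8.
    """
    missing = [g for g in model.panel if g not in expr.index]
    if missing:
        raise KeyError(f"panel genes missing from expression: {missing}")
    post = model.forest.predict_proba(expr.loc[model.panel].T)
    calls = np.asarray(model.classes)[np.argmax(post, axis=1)]
    out = pd.DataFrame(
        post, index=expr.columns,
        columns=[f"p_{c}" for c in model.classes],
    )
    out.insert(0, "cts", calls)
    out["high_confidence"] = post.max(axis=1) > 0.8
    return out


def brier_score(posteriors: np.ndarray | pd.DataFrame, labels, classes=None) -> float:
    """Multiclass Brier score: mean over samples of sum_c (p_c - 1[y=c])^2."""
    if isinstance(posteriors, pd.DataFrame):
        if classes is None:
            classes = [c[2:] if isinstance(c, str) and c.startswith("p_") else c
                       for c in posteriors.columns]
        posteriors = posteriors.to_numpy()
    post = np.asarray(posteriors, dtype=float)
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    classes = np.asarray(list(classes))
    labels = np.asarray([str(v) for v in labels]) if classes.dtype.kind in "UO" \
        else np.asarray(labels)
    cls = np.asarray([str(c) for c in classes]) if classes.dtype.kind in "UO" \
        else classes
    unknown = set(labels) - set(cls)
    if unknown:
        raise ValueError(f"label(s) outside model classes: {sorted(unknown)}")
    onehot = (labels[:, None] == cls[None, :]).astype(float)
    return float(((post - onehot) ** 2).sum(axis=1).mean())


def one_vs_all_auc(
    posteriors: pd.DataFrame | np.ndarray, labels, classes=None
) -> dict:
    """Per-subtype one-vs-all ROC AUC via the midrank Mann-Whitney formula."""
    if isinstance(posteriors, pd.DataFrame):
        if classes is None:
            classes = [c[2:] if isinstance(c, str) and c.startswith("p_") else c
                       for c in posteriors.columns]
        posteriors = posteriors.to_numpy()
    post = np.asarray(posteriors, dtype=float)
    labels = np.asarray([str(v) for v in labels])
    out = {}
    for j, c in enumerate(classes):
        pos = labels == str(c)
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError(f"one-class contrast for subtype {c}")
        ranks = stats.rankdata(post[:, j])
        out[c] = float(
            (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        )
    return out
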