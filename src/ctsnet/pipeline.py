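"""End-to-end orchestration: simulate -> harmonize -> network -> Markov
consensus -> core samples -> classifier -> prediction.

`run_pipeline` executes the full consensus-subtyping workflow on a cohort
(synthetic by default) and returns every intermediate artifact, so the same
code path serves interactive analysis, the command-line interface and the
reproducibility checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import CTSModel, CVReport, cv_panel_selection, fit_final, predict, rank_genes
from .harmonize import combat_adjust
from .mcl import (
    ConsensusMap,
    SweepResult,
    graph_adjacency,
    identify_core_samples,
    inflation_sweep,
    map_clusters_to_cts,
)
from .network import build_network
from .synthetic import SimConfig, SyntheticCohort, generate_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    harmonized: pd.DataFrame
    graph: object
    sweep: SweepResult
    consensus: ConsensusMap
    core: dict
    cv_report: CVReport | None
    panel: list[str] | None
    model: CTSModel | None
    calls: pd.DataFrame | None

    @property
    def core_fraction(self) -> float:
        n = self.cohort.labels.shape[0]
        return sum(len(v) for v in self.core.values()) / n

    def core_labels(self) -> pd.Series:
        pairs = [(s, str(cts)) for cts, ids in self.core.items() for s in ids]
        idx, vals = zip(*pairs)
        return pd.Series(vals, index=list(idx), name="cts")


def run_pipeline(
    config: SimConfig | None = None,
    cohort: SyntheticCohort | None = None,
    n_boot: int = 0,
    seed: int = 0,
    train_classifier: bool = True,
    cv_grid: tuple[int, ...] | None = None,
    n_trees: int = 500,
    folds: int = 10,
) -> PipelineResult:
    """Run the consensus-subtyping workflow and collect all artifacts.

    The classifier is trained on core samples only and then applied to the
    whole cohort. ``n_boot=0`` skips the permutation p-values on network
    edges (the hypergeometric q-values drive the consensus mapping).
    """
    if cohort is None:
        cohort = generate_cohort(config if config is not None else
                                 SimConfig(seed=seed))
    harmonized, _ = combat_adjust(cohort.expression, cohort.batch)
    graph = build_network(cohort.labels, n_boot=n_boot, seed=seed)
    nodes, adjacency = graph_adjacency(graph)
    sweep = inflation_sweep(adjacency)
    clusters = dict(zip(nodes, sweep.assignments[sweep.selected_inflation]))
    consensus = map_clusters_to_cts(graph, clusters)
    core = identify_core_samples(cohort.labels, consensus)

    cv_report = panel = model = calls = None
    if train_classifier:
        core_labels = pd.Series(
            {s: str(cts) for cts, ids in core.items() for s in ids},
            name="cts",
        )
        expr_core = harmonized[core_labels.index]
        kwargs = {} if cv_grid is None else {"grid": cv_grid}
        cv_report = cv_panel_selection(
            expr_core, core_labels, folds=folds, n_trees=n_trees, seed=seed,
            **kwargs,
        )
        ranking = rank_genes(expr_core, core_labels)
        panel = ranking.genes[: cv_report.selected_size]
        model = fit_final(expr_core, core_labels, panel, n_trees=n_trees,
                          seed=seed)
        calls = predict(model, harmonized)
    return PipelineResult(
        cohort=cohort, harmonized=harmonized, graph=graph, sweep=sweep,
        consensus=consensus, core=core, cv_report=cv_report, panel=panel,
        model=model, calls=calls,
    )
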