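"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices travel as TSV (genes as rows, first column the gene
id), subtype labels as long CSV (sample_id, system, label), clinical tables
as CSV, gene sets as GMT, single-cell counts as MatrixMarket plus a cell
annotation CSV, and fitted artifacts as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_labels_csv(path) -> pd.DataFrame:
    """Long (sample_id, system, label) CSV -> wide samples x systems frame."""
    long = pd.read_csv(path, dtype=str)
    wide = long.pivot(index="sample_id", columns="system", values="label")
    wide.columns.name = None
    return wide


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    long = labels.stack().rename("label").reset_index()
    long.columns = ["sample_id", "system", "label"]
    long.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_batch_csv(path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0].rename("batch")


def write_batch_csv(batch: pd.Series, path) -> None:
    batch.rename("batch").to_csv(path, index_label="sample_id")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_single_cell(adata, prefix) -> None:
    """MTX (cells x genes) + <prefix>_cells.csv + <prefix>_genes.csv."""
    prefix = Path(prefix)
    x = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scipy_io.mmwrite(str(prefix) + ".mtx", x)
    adata.obs.to_csv(str(prefix) + "_cells.csv", index_label="cell_id")
    pd.DataFrame(index=adata.var_names).to_csv(
        str(prefix) + "_genes.csv", index_label="gene_id"
    )


def read_single_cell(prefix):
    from anndata import AnnData

    prefix = Path(prefix)
    x = sparse.csr_matrix(scipy_io.mmread(str(prefix) + ".mtx"))
    obs = pd.read_csv(str(prefix) + "_cells.csv", index_col=0)
    var = pd.read_csv(str(prefix) + "_genes.csv", index_col=0)
    return AnnData(X=x, obs=obs, var=var)


def write_edge_list_tsv(graph: nx.Graph, path) -> None:
    rows = []
    for (sys_a, sub_a), (sys_b, sub_b), data in graph.edges(data=True):
        rows.append(
            {
                "system_a": sys_a, "subtype_a": sub_a,
                "system_b": sys_b, "subtype_b": sub_b,
                "jaccard": data["jaccard"], "p_boot": data["p_boot"],
                "p_hyper": data["p_hyper"], "q_hyper": data["q_hyper"],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    g = nx.Graph()
    for node, data in graph.nodes(data=True):
        g.add_node("|".join(node), system=data["system"],
                   subtype=data["subtype"], size=int(data["size"]))
    for u, v, data in graph.edges(data=True):
        g.add_edge("|".join(u), "|".join(v),
                   **{k: float(val) if isinstance(val, (int, float, np.floating))
                      else val for k, val in data.items()})
    nx.write_graphml(g, path)


def write_consensus_map_json(consensus, path) -> None:
    payload = {
        "cts_of_cluster": {str(k): v for k, v in consensus.cts_of_cluster.items()},
        "members": {
            str(cts): sorted(["|".join(n) for n in mem])
            for cts, mem in consensus.members.items()
        },
        "unclustered": sorted("|".join(n) for n in consensus.unclustered),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_model_json(model, path) -> None:
    Path(path).write_text(json.dumps(model.to_metadata(), indent=2))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
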