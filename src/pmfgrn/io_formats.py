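"""Readers and writers for the external formats, and label reconciliation.

Expression matrices are accepted as Matrix Market MTX (with plain-text
row/column label files), dense TSV, or H5AD (cells x genes, raw counts).
Networks use the crosstab convention — a dense TSV with gene rows and TF
columns — which matches how curated databases such as YEASTRACT are usually
distributed; an edge-list reader (gene, TF, value) is also provided and
converted internally.  Network entries are binarized on read by
``|entry| > 0`` so signed (activation/repression) files are handled.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, PriorNetwork
from .posterior import PosteriorSummary, threshold_network

logger = logging.getLogger("pmfgrn")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_labels(path: Path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([line.strip() for line in fh if line.strip()], dtype=object)


def read_expression(path, fmt: str | None = None, transpose: bool = False,
                    cell_labels=None, gene_labels=None) -> ExpressionMatrix:
    """Read an expression matrix; orientation is cells x genes.

    ``fmt`` is inferred from the suffix when omitted (.mtx, .tsv, .h5ad).
    For MTX, row/column label files default to ``<stem>_rows.txt`` and
    ``<stem>_cols.txt`` next to the matrix.  Set ``transpose`` for files
    stored genes x cells.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".tsv": "tsv", ".h5ad": "h5ad"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")

    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                            dtype=float)
        rows = _read_labels(Path(cell_labels) if cell_labels
                            else path.with_name(path.stem + "_rows.txt"))
        cols = _read_labels(Path(gene_labels) if gene_labels
                            else path.with_name(path.stem + "_cols.txt"))
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        rows = np.asarray(df.index.astype(str), dtype=object)
        cols = np.asarray(df.columns.astype(str), dtype=object)
    elif fmt == "h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
        x = adata.X
        values = np.asarray(x.todense() if scipy.sparse.issparse(x) else x,
                            dtype=float)
        rows = np.asarray(adata.obs_names.astype(str), dtype=object)
        cols = np.asarray(adata.var_names.astype(str), dtype=object)
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")

    if transpose:
        values = values.T
        rows, cols = cols, rows
    if values.shape[0] != len(rows) or values.shape[1] != len(cols):
        raise ValueError(
            f"label/dimension mismatch: matrix {values.shape}, "
            f"{len(rows)} row labels, {len(cols)} column labels"
        )
    W = ExpressionMatrix(values, rows, cols)
    logger.info("read expression %s: %d cells x %d genes", path.name,
                W.n_cells, W.n_genes)
    return W


def write_expression(W: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write an expression matrix as MTX (+ label files) or dense TSV."""
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".tsv": "tsv"}.get(path.suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(W.values))
        for name, labels in ((path.stem + "_rows.txt", W.cell_ids),
                             (path.stem + "_cols.txt", W.gene_ids)):
            with open(path.with_name(name), "w") as fh:
                fh.write("\n".join(str(x) for x in labels) + "\n")
    elif fmt == "tsv":
        pd.DataFrame(W.values, index=W.cell_ids, columns=W.gene_ids).to_csv(
            path, sep="\t")
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network_crosstab(path) -> PriorNetwork:
    """Read a genes x TFs crosstab TSV, binarizing entries by |entry| > 0."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"duplicate labels in network file {path}")
    entries = (df.to_numpy(dtype=float) != 0).astype(float)
    return PriorNetwork(entries,
                        np.asarray(df.index.astype(str), dtype=object),
                        np.asarray(df.columns.astype(str), dtype=object))


def read_network_edge_list(path, gene_col: int = 0, tf_col: int = 1) -> PriorNetwork:
    """Read a (gene, TF[, value]) edge list and convert to a crosstab."""
    df = pd.read_csv(Path(path), sep="\t", header=None, comment="#")
    genes = sorted(df.iloc[:, gene_col].astype(str).unique())
    tfs = sorted(df.iloc[:, tf_col].astype(str).unique())
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: j for j, t in enumerate(tfs)}
    entries = np.zeros((len(genes), len(tfs)))
    for _, row in df.iterrows():
        entries[gi[str(row.iloc[gene_col])], ti[str(row.iloc[tf_col])]] = 1.0
    return PriorNetwork(entries, np.asarray(genes, dtype=object),
                        np.asarray(tfs, dtype=object))


def write_network_crosstab(network: PriorNetwork, path) -> None:
    pd.DataFrame(network.entries, index=network.gene_ids,
                 columns=network.tf_ids).to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# label reconciliation
# ---------------------------------------------------------------------------

class LabelReconciliation:
    """Shared gene axis between an expression matrix and a network.

    The model's gene axis is the lexicographically sorted intersection; the
    TF axis is taken from the network.  Everything dropped is reported.
    """

    def __init__(self, shared_genes, expression_index_map, prior_index_map,
                 dropped_from_expression, dropped_from_prior):
        self.shared_genes = shared_genes
        self.expression_index_map = expression_index_map
        self.prior_index_map = prior_index_map
        self.dropped_from_expression = dropped_from_expression
        self.dropped_from_prior = dropped_from_prior


def reconcile_labels(W: ExpressionMatrix, prior: PriorNetwork) -> LabelReconciliation:
    expr_genes = W.gene_ids.tolist()
    prior_genes = prior.gene_ids.tolist()
    shared = sorted(set(expr_genes) & set(prior_genes))
    if not shared:
        raise ValueError("expression matrix and network share no genes")
    e_idx = {g: i for i, g in enumerate(expr_genes)}
    p_idx = {g: i for i, g in enumerate(prior_genes)}
    rec = LabelReconciliation(
        shared_genes=shared,
        expression_index_map={g: e_idx[g] for g in shared},
        prior_index_map={g: p_idx[g] for g in shared},
        dropped_from_expression=sorted(set(expr_genes) - set(shared)),
        dropped_from_prior=sorted(set(prior_genes) - set(shared)),
    )
    logger.info("reconciled labels: %d shared genes, %d dropped from expression,"
                " %d dropped from prior", len(shared),
                len(rec.dropped_from_expression), len(rec.dropped_from_prior))
    return rec


# ---------------------------------------------------------------------------
# posterior outputs
# ---------------------------------------------------------------------------

def write_posterior(summary: PosteriorSummary, out_dir,
                    edge_threshold: float = 0.9) -> dict:
    """Write posterior outputs as TSV crosstabs plus an edge list and metadata.

    Produces A_mean.tsv, A_var.tsv, B_mean.tsv (genes x TFs), tfa.tsv
    (cells x TFs), edges.tsv (entries with probability >= edge_threshold)
    and run_meta.json recording config, seeds and stopping information.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat, index in (
        ("A_mean", summary.A_mean, summary.gene_ids),
        ("A_var", summary.A_var, summary.gene_ids),
        ("B_mean", summary.B_mean, summary.gene_ids),
        ("tfa", summary.tfa, summary.cell_ids),
    ):
        cols = summary.tf_ids
        p = out_dir / f"{name}.tsv"
        pd.DataFrame(mat, index=index, columns=cols).to_csv(
            p, sep="\t", float_format="%.17g")
        paths[name] = p
    edges = threshold_network(summary, edge_threshold)
    paths["edges"] = out_dir / "edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)
    meta = dict(summary.meta)
    meta["edge_threshold"] = edge_threshold
    paths["run_meta"] = out_dir / "run_meta.json"
    with open(paths["run_meta"], "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return paths


def read_crosstab_frame(path) -> pd.DataFrame:
    """Read a real-valued crosstab TSV (e.g. A_mean.tsv) as a DataFrame."""
    return pd.read_csv(Path(path), sep="\t", index_col=0)
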