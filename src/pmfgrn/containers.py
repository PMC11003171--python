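"""Core data containers: expression matrices and binary interaction networks.

The model views the data as three matrices sharing label axes:

* an ``ExpressionMatrix`` ``W`` of raw UMI counts, cells x genes;
* a binary ``PriorNetwork`` (genes x TFs) of putative TF-target interactions,
  which parameterizes the prior over the interaction-probability matrix ``A``
  and anchors the identity of the latent TF columns;
* gold-standard networks for evaluation, which reuse ``PriorNetwork``.

Counts are kept raw (no normalization); the observation model absorbs
library-size variation through a per-cell depth factor instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_labels(labels, n: int, what: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(
            f"{what}: expected {n} labels, got shape {arr.shape}"
        )
    if len(set(arr.tolist())) != n:
        raise ValueError(f"{what}: labels must be unique")
    return arr


@dataclass
class ExpressionMatrix:
    """Raw single-cell count matrix, cells x genes, with axis labels."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (cells x genes)")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN entries")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        n, m = self.values.shape
        self.cell_ids = _as_labels(self.cell_ids, n, "cell_ids")
        self.gene_ids = _as_labels(self.gene_ids, m, "gene_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_order) -> "ExpressionMatrix":
        """Return a copy restricted/reordered to ``gene_order`` labels."""
        index = {g: i for i, g in enumerate(self.gene_ids.tolist())}
        try:
            cols = [index[g] for g in gene_order]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in expression matrix") from exc
        return ExpressionMatrix(
            self.values[:, cols], self.cell_ids.copy(), np.asarray(list(gene_order), dtype=object)
        )


@dataclass
class PriorNetwork:
    """Binary genes x TFs interaction matrix with axis labels.

    Used both for prior knowledge (hyperparameters of p(A)) and for gold
    standards; entries are strictly 0/1.
    """

    entries: np.ndarray
    gene_ids: np.ndarray
    tf_ids: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("network entries must be 2-D (genes x TFs)")
        if not np.isin(self.entries, (0.0, 1.0)).all():
            raise ValueError("network entries must be strictly binary (0/1)")
        m, k = self.entries.shape
        self.gene_ids = _as_labels(self.gene_ids, m, "gene_ids")
        self.tf_ids = _as_labels(self.tf_ids, k, "tf_ids")

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.entries.shape[1]

    @property
    def n_positives(self) -> int:
        return int(self.entries.sum())

    @property
    def density(self) -> float:
        return float(self.entries.mean())

    def copy(self) -> "PriorNetwork":
        return PriorNetwork(
            self.entries.copy(), self.gene_ids.copy(), self.tf_ids.copy()
        )

    def subset_genes(self, gene_order) -> "PriorNetwork":
        index = {g: i for i, g in enumerate(self.gene_ids.tolist())}
        try:
            rows = [index[g] for g in gene_order]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in network") from exc
        return PriorNetwork(
            self.entries[rows], np.asarray(list(gene_order), dtype=object), self.tf_ids.copy()
        )
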