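"""Core data containers: expression matrices, prior networks, aligned datasets.

These are deliberately lightweight wrappers around numpy / scipy.sparse with
validated identifier indices, so that every downstream operation can assume
aligned, duplicate-free gene and cell namespaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of non-negative expression values.

    Values may be raw counts or log-normalized; ``is_lognorm`` records which.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    is_lognorm: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if sp.issparse(self.values):  # pragma: no cover - asarray densifies
            self.values = self.values.toarray()
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_idx=None, gene_idx=None) -> "ExpressionMatrix":
        v = self.values
        cells = self.cell_ids
        genes = self.gene_ids
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            v = v[cell_idx]
            cells = cells[cell_idx]
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            v = v[:, gene_idx]
            genes = genes[gene_idx]
        return ExpressionMatrix(v.copy(), cells.copy(), genes.copy(), self.is_lognorm)


@dataclass
class PriorGRN:
    """A signed sparse TF x gene prior network.

    Entries are ternary {-1, 0, +1} (sign encodes activation/repression) or
    binary {0, 1} when signs were collapsed.
    """

    tf_ids: np.ndarray
    gene_ids: np.ndarray
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.weights = sp.csr_matrix(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("prior weight shape inconsistent with identifier lengths")

    @property
    def n_tfs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_genes(self) -> int:
        return self.weights.shape[1]

    def dense(self) -> np.ndarray:
        return self.weights.toarray()

    def subset(self, tf_idx=None, gene_idx=None) -> "PriorGRN":
        w = self.weights
        tfs = self.tf_ids
        genes = self.gene_ids
        if tf_idx is not None:
            tf_idx = np.asarray(tf_idx)
            w = w[tf_idx]
            tfs = tfs[tf_idx]
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            w = w[:, gene_idx]
            genes = genes[gene_idx]
        return PriorGRN(tfs.copy(), genes.copy(), w.copy())


@dataclass
class AlignedDataset:
    """Expression and prior restricted to a common, ordered gene namespace."""

    expression: ExpressionMatrix
    prior: PriorGRN
    train_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    val_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if not np.array_equal(self.expression.gene_ids, self.prior.gene_ids):
            raise ValueError("expression and prior gene identifiers differ in content or order")
        self.train_index = np.asarray(self.train_index, dtype=int)
        self.val_index = np.asarray(self.val_index, dtype=int)

    @property
    def n_cells(self) -> int:
        return self.expression.n_cells

    @property
    def n_genes(self) -> int:
        return self.expression.n_genes

    @property
    def n_tfs(self) -> int:
        return self.prior.n_tfs


@dataclass
class GroundTruthGRN:
    """Binary TF x gene matrix of true regulatory edges (simulation truth)."""

    tf_ids: np.ndarray
    gene_ids: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.edges = np.asarray(self.edges)
        if not np.isin(self.edges, [0, 1]).all():
            raise ValueError("ground-truth edges must be binary")
        if self.edges.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValueError("edge matrix shape inconsistent with identifier lengths")
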