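"""Input handling: prior-network edge lists, expression matrices, joint filtering.

The expression matrix and the signed TF-target prior must end up on a single,
identically ordered gene namespace before model fitting; :func:`filter_and_align`
applies the quality filters (minimum cells per gene, genes per cell, targets
per TF) and produces that alignment.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._containers import AlignedDataset, ExpressionMatrix, PriorGRN

__all__ = [
    "load_prior_edges",
    "load_expression",
    "load_labels",
    "log1p_cpm",
    "filter_and_align",
    "split_train_val",
]


def load_prior_edges(path, sign_mode: str = "ternary") -> PriorGRN:
    """Read a TF-target edge list (TSV: source, target, weight/sign).

    Duplicate (TF, gene) pairs collapse by sign majority, ties resolving to +1.
    ``sign_mode='binary'`` collapses all signs to +1 after de-duplication.
    """
    if sign_mode not in ("binary", "ternary"):
        raise ValueError(f"sign_mode must be 'binary' or 'ternary', got {sign_mode!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty prior edge file: {path}")
    if df.shape[0] == 0:
        raise ValueError(f"prior edge file has no edges: {path}")
    if df.shape[1] < 3:
        raise ValueError(
            f"prior edge file needs (source, target, weight) columns, found {list(df.columns)}"
        )
    df = df.iloc[:, :3].copy()
    df.columns = ["source", "target", "weight"]
    if df[["source", "target"]].isna().any().any():
        bad = int(df[["source", "target"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"malformed prior edge row at line {bad} of {path}")
    w = pd.to_numeric(df["weight"], errors="coerce")
    if w.isna().any():
        bad = int(w.isna().idxmax()) + 2  # +2: header line and 1-based numbering
        raise ValueError(f"non-numeric weight at line {bad} of {path}")
    df["sign"] = np.sign(w).replace(0, 1.0)

    # sign-majority collapse of duplicates; ties -> +1
    agg = df.groupby(["source", "target"], sort=False)["sign"].sum()
    signs = np.where(agg.values >= 0, 1.0, -1.0)
    if sign_mode == "binary":
        signs = np.ones_like(signs)

    tfs = pd.unique(df["source"].astype(str))
    genes = pd.unique(df["target"].astype(str))
    tf_pos = {t: i for i, t in enumerate(tfs)}
    gene_pos = {g: j for j, g in enumerate(genes)}
    rows = [tf_pos[str(t)] for t, _ in agg.index]
    cols = [gene_pos[str(g)] for _, g in agg.index]
    mat = sp.csr_matrix((signs, (rows, cols)), shape=(len(tfs), len(genes)))
    return PriorGRN(tfs, genes, mat)


def write_prior_edges(prior: PriorGRN, path) -> None:
    """Write a PriorGRN back to a (source, target, weight) TSV."""
    coo = prior.weights.tocoo()
    df = pd.DataFrame(
        {
            "source": prior.tf_ids[coo.row],
            "target": prior.gene_ids[coo.col],
            "weight": coo.data,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_expression(path, is_lognorm: bool | None = None) -> ExpressionMatrix:
    """Load expression as cells x genes from .h5ad, .mtx (+ sidecar TSVs) or CSV/TSV.

    For MatrixMarket input, ``genes.tsv`` and ``barcodes.tsv`` are expected next
    to the .mtx file (CellRanger layout, genes x cells orientation).
    """
    path = Path(path)
    if path.suffix == ".h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        vals = ad.X.toarray() if sp.issparse(ad.X) else np.asarray(ad.X)
        lognorm = bool(vals.max() < 50) if is_lognorm is None else is_lognorm
        return ExpressionMatrix(vals, np.asarray(ad.obs_names), np.asarray(ad.var_names), lognorm)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None).iloc[:, 0]
        cells = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None).iloc[:, 0]
        vals = np.asarray(mat.todense()).T  # mtx stored genes x cells
        return ExpressionMatrix(vals, cells.to_numpy(), genes.to_numpy(), bool(is_lognorm))
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64), df.index.to_numpy(), df.columns.to_numpy(), bool(is_lognorm)
    )


def load_labels(path) -> pd.Series:
    """Two-column TSV (cell_id, label) -> Series indexed by cell id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label file needs (cell_id, label) columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str).to_numpy())


def log1p_cpm(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Convenience log1p(CPM/CP10K) transform for raw-count input."""
    if expr.is_lognorm:
        return expr
    totals = expr.values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    vals = np.log1p(expr.values / totals * scale)
    return ExpressionMatrix(vals, expr.cell_ids, expr.gene_ids, is_lognorm=True)


def filter_and_align(
    expr: ExpressionMatrix,
    prior: PriorGRN,
    min_cells_per_gene: int = 10,
    min_genes_per_cell: int = 3,
    min_targets_per_tf: int = 10,
    uppercase: bool = False,
) -> AlignedDataset:
    """Jointly filter expression and prior, returning gene-aligned copies.

    Genes are kept when expressed (value > 0) in at least ``min_cells_per_gene``
    cells and covered by at least one TF in the prior; cells when they express
    at least ``min_genes_per_cell`` retained genes; TFs when they retain at
    least ``min_targets_per_tf`` targets. The gene filter is re-checked once
    against the retained cells, then the TF filter is applied.
    """
    gene_ids_e = expr.gene_ids
    gene_ids_p = prior.gene_ids
    if uppercase:
        gene_ids_e = np.array([g.upper() for g in gene_ids_e], dtype=object)
        gene_ids_p = np.array([g.upper() for g in gene_ids_p], dtype=object)
        expr = ExpressionMatrix(expr.values, expr.cell_ids, gene_ids_e, expr.is_lognorm)
        prior = PriorGRN(prior.tf_ids, gene_ids_p, prior.weights)

    covered = set(gene_ids_p[np.asarray((prior.weights != 0).sum(axis=0)).ravel() > 0])
    expressed_in = (expr.values > 0).sum(axis=0)
    gene_keep = (expressed_in >= min_cells_per_gene) & np.array(
        [g in covered for g in gene_ids_e]
    )
    if not gene_keep.any():
        raise ValueError("no genes survive the gene filter (expression + prior coverage)")

    cell_keep = (expr.values[:, gene_keep] > 0).sum(axis=1) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError("no cells survive the cell filter")

    # re-check gene expression counts over the retained cells only
    expressed_in2 = (expr.values[cell_keep][:, gene_keep] > 0).sum(axis=0)
    gene_keep_idx = np.flatnonzero(gene_keep)[expressed_in2 >= min_cells_per_gene]
    if gene_keep_idx.size == 0:
        raise ValueError("no genes survive the gene filter re-check")

    expr_f = expr.subset(np.flatnonzero(cell_keep), gene_keep_idx)

    # align prior columns to the retained gene order, then apply the TF filter
    pos = {g: j for j, g in enumerate(gene_ids_p)}
    missing = [g for g in expr_f.gene_ids if g not in pos]
    if missing:  # genes required prior coverage above, so this cannot happen
        raise AssertionError(f"genes missing from prior after coverage filter: {missing[:5]}")
    col_order = np.array([pos[g] for g in expr_f.gene_ids])
    w = prior.weights[:, col_order]
    targets_per_tf = np.asarray((w != 0).sum(axis=1)).ravel()
    tf_keep = targets_per_tf >= min_targets_per_tf
    if not tf_keep.any():
        raise ValueError(
            f"no TFs retain >= {min_targets_per_tf} targets after gene/cell filtering"
        )
    prior_f = PriorGRN(prior.tf_ids[tf_keep], expr_f.gene_ids.copy(), w[tf_keep])
    return AlignedDataset(expr_f, prior_f)


def split_train_val(
    data: AlignedDataset, val_fraction: float = 0.15, seed: int = 0
) -> AlignedDataset:
    """Seeded uniform train/validation split over cells (default 85-15)."""
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    n = data.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    n_val = int(np.clip(round(val_fraction * n), 1, n - 1))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return AlignedDataset(data.expression, data.prior, train_index=train, val_index=val)
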