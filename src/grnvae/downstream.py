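"""Post-hoc analytics on inferred activities and networks.

Covers per-TF min-max scaling of GRN weights, differential TF activity
between cell groups (Wilcoxon rank-sum + Benjamini-Hochberg), TF-TF
co-regulation by cosine similarity of regulatory profiles, and cross
cell-type GRN similarity with hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import false_discovery_control, mannwhitneyu

from .model import TFActivityMatrix

__all__ = [
    "ScaledGRN",
    "scale_grn",
    "differential_tf_activity",
    "tf_coregulation_network",
    "grn_similarity",
    "top_targets",
]

_LFC_EPS = 1e-9  # pseudo-count; ReLU activities can be exactly zero


@dataclass
class ScaledGRN:
    """Per-TF min-max scaled weights in [0, 1] alongside the raw matrix."""

    weights: np.ndarray
    raw: np.ndarray


def scale_grn(w: np.ndarray) -> ScaledGRN:
    """Min-max scale each TF's outgoing weights to [0, 1] (constant rows -> 0)."""
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValueError("GRN weights must be finite")
    lo = w.min(axis=1, keepdims=True)
    hi = w.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(w)
    ok = span.ravel() > 0
    out[ok] = (w[ok] - lo[ok]) / span[ok]
    return ScaledGRN(out, w)


def differential_tf_activity(
    acts: TFActivityMatrix, groups, alpha: float = 0.05
) -> pd.DataFrame:
    """One-vs-rest differential TF activity per group.

    For each TF and group, a two-sided Wilcoxon rank-sum test compares
    in-group against out-of-group activities; P-values are BH-adjusted across
    TFs within each group. Retained rows (p_adj < alpha) are ranked by
    log2 fold change, descending.
    """
    from .model import _as_label_array

    labels = _as_label_array(groups, acts.cell_ids).astype(str)
    uniq = np.unique(labels)
    sizes = {g: int((labels == g).sum()) for g in uniq}
    usable = [g for g in uniq if sizes[g] >= 2]
    for g in uniq:
        if sizes[g] < 2:
            warnings.warn(f"group {g!r} has fewer than 2 cells; excluded")
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 cells each")

    rows = []
    for g in usable:
        in_mask = labels == g
        a_in = acts.values[in_mask]
        a_out = acts.values[~in_mask]
        pvals = np.empty(acts.values.shape[1])
        lfcs = np.empty_like(pvals)
        for j in range(acts.values.shape[1]):
            x, y = a_in[:, j], a_out[:, j]
            if np.all(x == x[0]) and np.all(y == x[0]):
                pvals[j] = 1.0
            else:
                pvals[j] = mannwhitneyu(x, y, alternative="two-sided").pvalue
            lfcs[j] = np.log2((x.mean() + _LFC_EPS) / (y.mean() + _LFC_EPS))
        padj = false_discovery_control(pvals, method="bh")
        for j, tf in enumerate(acts.tf_ids):
            rows.append((tf, g, lfcs[j], pvals[j], padj[j]))

    table = pd.DataFrame(rows, columns=["tf", "group", "lfc", "p_raw", "p_adj"])
    retained = table[table["p_adj"] < alpha].copy()
    retained = retained.sort_values(["group", "lfc"], ascending=[True, False])
    retained["rank"] = retained.groupby("group").cumcount() + 1
    return retained.reset_index(drop=True)


def tf_coregulation_network(
    w: np.ndarray, tf_ids=None, threshold: float = 0.8
) -> pd.DataFrame:
    """TF pairs whose regulatory profiles have cosine similarity >= threshold.

    Zero-norm rows produce no edges; self-pairs are excluded; each unordered
    pair appears once.
    """
    if not -1 < threshold <= 1:
        raise ValueError("threshold must lie in (-1, 1]")
    w = np.asarray(w, dtype=np.float64)
    n = w.shape[0]
    if tf_ids is None:
        tf_ids = np.arange(n)
    norms = np.linalg.norm(w, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = (w @ w.T) / np.outer(norms, norms)
    sim[~np.isfinite(sim)] = -np.inf  # zero-norm rows never linked
    rows = [
        (tf_ids[i], tf_ids[j], float(sim[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if sim[i, j] >= threshold
    ]
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "cosine"])


def grn_similarity(grns: dict) -> tuple[pd.DataFrame, list]:
    """Pairwise Pearson similarity of cell-type GRNs + dendrogram leaf order.

    Each matrix's absolute values are min-max scaled per TF row, flattened,
    and correlated pairwise; average-linkage clustering on 1 - r distances
    gives the leaf order.
    """
    names = list(grns)
    if len(names) < 2:
        raise ValueError("need at least 2 GRNs to compare")
    shapes = {np.asarray(grns[n]).shape for n in names}
    if len(shapes) != 1:
        raise ValueError("all GRNs must share TF/gene indices (shapes differ)")
    flats = {}
    for n in names:
        v = scale_grn(np.abs(np.asarray(grns[n], dtype=np.float64))).weights.ravel()
        if np.all(v == v[0]):
            raise ValueError(f"GRN for {n!r} is constant after scaling; correlation undefined")
        flats[n] = v
    k = len(names)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = np.corrcoef(flats[names[i]], flats[names[j]])[0, 1]
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    order = [names[i] for i in leaves_list(linkage(dist, method="average"))]
    return pd.DataFrame(r, index=names, columns=names), order


def grn_dendrogram_newick(grns: dict) -> str:
    """Newick string for the average-linkage dendrogram of GRN similarities."""
    from skbio import TreeNode

    names = list(grns)
    sim, _ = grn_similarity(grns)
    dist = squareform(np.clip(1.0 - sim.to_numpy(), 0.0, None), checks=False)
    tree = TreeNode.from_linkage_matrix(linkage(dist, method="average"), names)
    return str(tree)


def top_targets(w: np.ndarray, tf_ids, gene_ids, fraction: float = 0.01) -> pd.DataFrame:
    """Top-ranked targets per TF (default top 1% by scaled weight), for export
    to external enrichment tools."""
    scaled = scale_grn(np.asarray(w, dtype=np.float64)).weights
    n_top = max(1, int(round(fraction * scaled.shape[1])))
    rows = []
    for i, tf in enumerate(tf_ids):
        order = np.argsort(-scaled[i], kind="stable")[:n_top]
        for rank, j in enumerate(order, 1):
            rows.append((tf, gene_ids[j], float(scaled[i, j]), rank))
    return pd.DataFrame(rows, columns=["tf", "target", "scaled_weight", "rank"])
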