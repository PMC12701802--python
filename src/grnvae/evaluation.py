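"""Benchmarking procedures: clustering of TF activities, dropout robustness,
GRN edge-recovery AUROC/AUPRC, stratified sketching, and knockdown scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    f1_score,
    normalized_mutual_info_score,
    roc_auc_score,
)
from sklearn.neighbors import NearestNeighbors

from ._containers import ExpressionMatrix, GroundTruthGRN
from .model import TFActivityMatrix

__all__ = [
    "ClusteringReport",
    "dropout_mask",
    "cluster_activities",
    "majority_vote_labels",
    "clustering_metrics",
    "grn_auroc_auprc",
    "stratified_sketch",
    "knockdown_evaluation",
]

_LFC_EPS = 1e-9


@dataclass
class ClusteringReport:
    resolution: float
    ari: float
    nmi: float
    macro_f1: float
    auc: float
    n_clusters: int


def dropout_mask(x: ExpressionMatrix, p: float, seed: int) -> ExpressionMatrix:
    """Bernoulli dropout: each entry kept with probability 1-p, else zeroed."""
    if not 0 <= p < 1:
        raise ValueError("dropout probability must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=x.values.shape)
    keep = u > p
    return ExpressionMatrix(x.values * keep, x.cell_ids, x.gene_ids, x.is_lognorm)


def _knn_graph(values: np.ndarray, k: int):
    """Undirected kNN graph (Euclidean) as an igraph Graph."""
    import igraph as ig

    n = values.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(values)
    _, idx = nn.kneighbors(values)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_activities(
    acts: TFActivityMatrix | np.ndarray,
    resolutions=(0.2, 3.0),
    k: int = 15,
    seed: int = 0,
) -> dict:
    """Leiden partitions of the activity kNN graph at each resolution.

    ``resolutions`` is any iterable of resolution parameters; the canonical
    benchmarking sweep covers 0.2-3.0.
    """
    import leidenalg

    values = acts.values if isinstance(acts, TFActivityMatrix) else np.asarray(acts, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    resolutions = list(resolutions)
    if any(r <= 0 for r in resolutions):
        raise ValueError("resolutions must be positive")
    g = _knn_graph(values, k)
    out = {}
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        out[res] = np.asarray(part.membership)
    return out


def resolution_sweep(start: float = 0.2, stop: float = 3.0, step: float = 0.2) -> list:
    """The default Leiden resolution grid, 0.2-3.0 inclusive."""
    n = int(round((stop - start) / step))
    return [round(start + i * step, 10) for i in range(n + 1)]


def majority_vote_labels(pred_clusters, true_labels) -> np.ndarray:
    """Assign each cell its cluster's modal true label (ties -> lexicographic)."""
    pred = np.asarray(pred_clusters)
    truth = np.asarray(true_labels, dtype=object)
    if pred.shape[0] != truth.shape[0]:
        raise ValueError("cluster and label vectors must cover the same cells")
    assigned = np.empty_like(truth)
    for c in np.unique(pred):
        members = pred == c
        labels, counts = np.unique(truth[members].astype(str), return_counts=True)
        # np.unique sorts lexicographically, so argmax picks the smallest on ties
        assigned[members] = labels[np.argmax(counts)]
    return assigned


def clustering_metrics(assigned, truth, resolution: float = float("nan"),
                       n_clusters: int | None = None) -> ClusteringReport:
    """ARI / NMI / macro-F1 / macro one-vs-rest AUC of assigned vs true labels.

    The AUC treats the assigned-label indicator as the score for each class
    (a coarse, label-level construction; reported for completeness).
    """
    assigned = np.asarray(assigned).astype(str)
    truth = np.asarray(truth).astype(str)
    if assigned.shape[0] != truth.shape[0]:
        raise ValueError("length mismatch")
    classes = np.unique(truth)
    if classes.size < 2:
        raise ValueError("ARI/NMI undefined for a single true class")
    ari = adjusted_rand_score(truth, assigned)
    nmi = normalized_mutual_info_score(truth, assigned)
    macro_f1 = f1_score(truth, assigned, labels=classes, average="macro", zero_division=0)
    onehot_true = (truth[:, None] == classes[None, :]).astype(float)
    onehot_pred = (assigned[:, None] == classes[None, :]).astype(float)
    aucs = []
    for j in range(classes.size):
        if onehot_true[:, j].min() == onehot_true[:, j].max():
            continue
        aucs.append(roc_auc_score(onehot_true[:, j], onehot_pred[:, j]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    return ClusteringReport(
        resolution, float(ari), float(nmi), float(macro_f1), auc,
        int(np.unique(assigned).size) if n_clusters is None else n_clusters,
    )


def grn_auroc_auprc(
    pred: np.ndarray | pd.DataFrame,
    truth: GroundTruthGRN | np.ndarray,
    pred_tf_ids=None,
    pred_gene_ids=None,
) -> tuple[float, float]:
    """AUROC and AUPRC of |predicted weights| against a binary truth network.

    Evaluation is restricted to the intersection of TF and gene identifiers
    when both sides carry them; ties are handled by midranking (AUROC) and
    score-grouped precision-recall steps (AUPRC).
    """
    if isinstance(pred, pd.DataFrame):
        pred_tf_ids = pred.index.to_numpy()
        pred_gene_ids = pred.columns.to_numpy()
        pred = pred.to_numpy()
    pred = np.asarray(pred, dtype=np.float64)

    if isinstance(truth, GroundTruthGRN) and pred_tf_ids is not None:
        tf_common = [t for t in truth.tf_ids if t in set(pred_tf_ids)]
        gene_common = [g for g in truth.gene_ids if g in set(pred_gene_ids)]
        if not tf_common or not gene_common:
            raise ValueError("no TF/gene overlap between prediction and truth")
        t_tf = {t: i for i, t in enumerate(truth.tf_ids)}
        t_ge = {g: j for j, g in enumerate(truth.gene_ids)}
        p_tf = {t: i for i, t in enumerate(pred_tf_ids)}
        p_ge = {g: j for j, g in enumerate(pred_gene_ids)}
        y = truth.edges[np.ix_([t_tf[t] for t in tf_common], [t_ge[g] for g in gene_common])]
        s = pred[np.ix_([p_tf[t] for t in tf_common], [p_ge[g] for g in gene_common])]
    else:
        y = truth.edges if isinstance(truth, GroundTruthGRN) else np.asarray(truth)
        s = pred
        if y.shape != s.shape:
            raise ValueError("prediction and truth shapes differ and no identifiers given")

    y = y.ravel().astype(int)
    s = np.abs(s.ravel())
    if y.min() == y.max():
        raise ValueError("ground truth is all-positive or all-negative on the intersection")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def stratified_sketch(
    x: ExpressionMatrix | np.ndarray,
    n_subsets: int = 5,
    seed: int = 0,
    resolution: float = 1.0,
    n_pcs: int = 50,
    k: int = 15,
) -> list:
    """Partition cells into ``n_subsets`` proportional stratified subsets.

    Pseudo-clusters come from Leiden on a PCA embedding; each cluster's cells
    are split across the subsets proportionally (seeded uniform split within
    cluster), so every subset mirrors the global cluster composition to
    within one cell per cluster. A geometric-sketching backend can replace
    the within-cluster split via ``_within_cluster_order``.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n = values.shape[0]
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if n_subsets > n:
        raise ValueError("more subsets than cells")
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, min(values.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(values) if n_pcs >= 1 else values
    clusters = cluster_activities(emb, resolutions=[resolution], k=k, seed=seed)[resolution]

    rng = np.random.default_rng(seed)
    subsets: list[list[int]] = [[] for _ in range(n_subsets)]
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        order = _within_cluster_order(members, rng)
        # round-robin over a shuffled order: subset sizes differ by at most 1
        for pos, cell in enumerate(order):
            subsets[pos % n_subsets].append(int(cell))
    return [np.sort(np.asarray(s)) for s in subsets]


def _within_cluster_order(members: np.ndarray, rng) -> np.ndarray:
    """Hook for sketching backends: default is a seeded uniform shuffle."""
    return rng.permutation(members)


def knockdown_evaluation(
    acts_ctrl: TFActivityMatrix, acts_kd: TFActivityMatrix, perturbed_tf
) -> tuple[float, float]:
    """Log2 fold change and rank-sum P-value of one TF's activity, kd vs ctrl."""
    for acts in (acts_ctrl, acts_kd):
        if perturbed_tf not in set(acts.tf_ids):
            raise ValueError(f"TF {perturbed_tf!r} absent from activity matrix")
        if acts.values.shape[0] == 0:
            raise ValueError("empty condition")
    j_c = int(np.flatnonzero(acts_ctrl.tf_ids == perturbed_tf)[0])
    j_k = int(np.flatnonzero(acts_kd.tf_ids == perturbed_tf)[0])
    a_c = acts_ctrl.values[:, j_c]
    a_k = acts_kd.values[:, j_k]
    lfc = float(np.log2((a_k.mean() + _LFC_EPS) / (a_c.mean() + _LFC_EPS)))
    if np.all(a_k == a_k[0]) and np.all(a_c == a_k[0]):
        p = 1.0
    else:
        p = float(mannwhitneyu(a_k, a_c, alternative="two-sided").pvalue)
    return lfc, p
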