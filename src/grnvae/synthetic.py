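"""Simulation of single-cell expression from a known regulatory network.

The generative process mirrors the model's own assumptions (expression is a
noisy linear read-out of non-negative TF activities through a signed weight
matrix, with Bernoulli dropout), so recovery tests probe the inference
machinery rather than likelihood mismatch:

1. a signed truth GRN is sampled (``edges_per_tf`` targets per TF, log-normal
   magnitudes, a configurable fraction of repressive edges), optionally with
   per-cluster rewired variants;
2. per-cell TF activities are Gamma-distributed, with a higher mean where the
   TF is "on" in the cell's cluster (the first ``n_clusters`` TFs are each
   exclusively on in one cluster, guaranteeing cluster-specific regulators);
3. expression = activities . W_truth + Gaussian noise, clipped at zero;
4. Bernoulli dropout zeroes entries with probability ``dropout_p``;
5. the exported prior is the truth support with ``prior_corruption`` of each
   TF's edges replaced by random false edges.

All randomness derives from ``seed`` through fixed substreams, so a
knockdown re-simulation reuses the identical noise and dropout draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from ._containers import ExpressionMatrix, GroundTruthGRN, PriorGRN

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "simulate_knockdown"]

_GAMMA_SHAPE = 4.0  # shape of the per-cell activity distribution


@dataclass
class SimulationConfig:
    n_cells: int = 600
    n_genes: int = 200
    n_tfs: int = 15
    n_clusters: int = 3
    edges_per_tf: int = 15
    sign_fraction_negative: float = 0.3
    activity_mean_on: float = 5.0
    activity_mean_off: float = 0.5
    noise_sd: float = 0.5
    dropout_p: float = 0.0
    prior_corruption: float = 0.0
    cluster_rewire_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.edges_per_tf > self.n_genes:
            raise ValueError("edges_per_tf cannot exceed n_genes")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        if not 0 <= self.prior_corruption <= 1:
            raise ValueError("prior_corruption must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    truth_grn: GroundTruthGRN | dict
    truth_weights: np.ndarray | dict
    truth_activities: np.ndarray
    labels: np.ndarray
    prior: PriorGRN
    config: SimulationConfig
    tf_on: np.ndarray = field(default=None)  # n_tfs x n_clusters indicator

    @property
    def tf_ids(self) -> np.ndarray:
        return self.prior.tf_ids


def _substream(seed: int, stream: int):
    return np.random.default_rng([int(seed) % (2**31), stream])


def _sample_grn(cfg: SimulationConfig, rng) -> np.ndarray:
    w = np.zeros((cfg.n_tfs, cfg.n_genes))
    for i in range(cfg.n_tfs):
        targets = rng.choice(cfg.n_genes, size=cfg.edges_per_tf, replace=False)
        signs = np.where(rng.uniform(size=cfg.edges_per_tf) < cfg.sign_fraction_negative, -1.0, 1.0)
        mags = rng.lognormal(mean=0.0, sigma=0.4, size=cfg.edges_per_tf)
        w[i, targets] = signs * mags
    return w


def _rewire(w: np.ndarray, fraction: float, rng, cfg: SimulationConfig) -> np.ndarray:
    out = w.copy()
    n_move = int(round(fraction * cfg.edges_per_tf))
    for i in range(out.shape[0]):
        current = np.flatnonzero(out[i])
        drop = rng.choice(current, size=min(n_move, current.size), replace=False)
        out[i, drop] = 0.0
        free = np.flatnonzero(out[i] == 0)
        add = rng.choice(free, size=drop.size, replace=False)
        signs = np.where(rng.uniform(size=drop.size) < cfg.sign_fraction_negative, -1.0, 1.0)
        out[i, add] = signs * rng.lognormal(mean=0.0, sigma=0.4, size=drop.size)
    return out


def _expression(cfg: SimulationConfig, activities: np.ndarray, labels: np.ndarray,
                weights) -> np.ndarray:
    """Deterministic re-generation of expression from activities and seed."""
    if isinstance(weights, dict):
        x = np.empty((cfg.n_cells, cfg.n_genes))
        for c, w in weights.items():
            mask = labels == c
            x[mask] = activities[mask] @ w
    else:
        x = activities @ weights
    noise = _substream(cfg.seed, 2).normal(0.0, cfg.noise_sd, size=x.shape)
    x = np.clip(x + noise, 0.0, None)
    if cfg.dropout_p > 0:
        u = _substream(cfg.seed, 3).uniform(size=x.shape)
        x = x * (u > cfg.dropout_p)
    return x


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a dataset with known GRN, activities, labels and prior."""
    cfg = config
    rng_grn = _substream(cfg.seed, 0)
    rng_act = _substream(cfg.seed, 1)
    rng_cor = _substream(cfg.seed, 4)

    tf_ids = np.array([f"TF{i:03d}" for i in range(cfg.n_tfs)], dtype=object)
    gene_ids = np.array([f"g{j:04d}" for j in range(cfg.n_genes)], dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    cluster_names = np.array([f"c{c}" for c in range(cfg.n_clusters)], dtype=object)

    base_w = _sample_grn(cfg, rng_grn)
    if cfg.cluster_rewire_fraction > 0:
        weights = {
            cluster_names[c]: _rewire(base_w, cfg.cluster_rewire_fraction, rng_grn, cfg)
            for c in range(cfg.n_clusters)
        }
        truth = {
            name: GroundTruthGRN(tf_ids, gene_ids, (w != 0).astype(int))
            for name, w in weights.items()
        }
    else:
        weights = base_w
        truth = GroundTruthGRN(tf_ids, gene_ids, (base_w != 0).astype(int))

    # on/off pattern: first n_clusters TFs are cluster-exclusive markers
    on = rng_act.uniform(size=(cfg.n_tfs, cfg.n_clusters)) < 0.5
    for c in range(min(cfg.n_clusters, cfg.n_tfs)):
        on[c] = False
        on[c, c] = True
    all_off = ~on.any(axis=1)
    on[all_off, rng_act.integers(0, cfg.n_clusters, size=all_off.sum())] = True

    labels_int = np.repeat(np.arange(cfg.n_clusters), -(-cfg.n_cells // cfg.n_clusters))
    labels_int = labels_int[rng_act.permutation(cfg.n_cells)]
    labels = cluster_names[labels_int]

    means = np.where(on[:, labels_int].T, cfg.activity_mean_on, cfg.activity_mean_off)
    activities = rng_act.gamma(_GAMMA_SHAPE, means / _GAMMA_SHAPE)

    x = _expression(cfg, activities, labels, weights)
    expression = ExpressionMatrix(x, cell_ids, gene_ids, is_lognorm=True)

    support = (base_w != 0).astype(float) * np.sign(base_w)
    prior_w = support.copy()
    if cfg.prior_corruption > 0:
        n_move = int(round(cfg.prior_corruption * cfg.edges_per_tf))
        for i in range(cfg.n_tfs):
            current = np.flatnonzero(prior_w[i])
            drop = rng_cor.choice(current, size=min(n_move, current.size), replace=False)
            prior_w[i, drop] = 0.0
            # false edges only: never re-add a (dropped) truth position
            free = np.flatnonzero((prior_w[i] == 0) & (support[i] == 0))
            add = rng_cor.choice(free, size=drop.size, replace=False)
            prior_w[i, add] = np.where(rng_cor.uniform(size=drop.size) < 0.5, -1.0, 1.0)
    prior = PriorGRN(tf_ids, gene_ids, sp.csr_matrix(prior_w))

    return SimulatedDataset(expression, truth, weights, activities, labels, prior, cfg, on)


def simulate_knockdown(dataset: SimulatedDataset, tf, factor: float = 0.1,
                       cells=None) -> SimulatedDataset:
    """Suppress one TF's truth activity and regenerate expression.

    The noise and dropout substreams are re-derived from the same seed, so
    unperturbed TFs yield (near-)identical expression and the knockdown's
    effect is isolated.
    """
    if not 0 <= factor <= 1:
        raise ValueError("knockdown factor must lie in [0, 1]")
    tf_idx = np.flatnonzero(dataset.tf_ids == tf)
    if tf_idx.size == 0:
        raise ValueError(f"unknown TF {tf!r}")
    cfg = dataset.config
    cells = np.arange(cfg.n_cells) if cells is None else np.asarray(cells)
    activities = dataset.truth_activities.copy()
    activities[np.ix_(cells, tf_idx)] *= factor
    x = _expression(cfg, activities, dataset.labels, dataset.truth_weights)
    expression = ExpressionMatrix(
        x, dataset.expression.cell_ids, dataset.expression.gene_ids, is_lognorm=True
    )
    return SimulatedDataset(
        expression, dataset.truth_grn, dataset.truth_weights, activities,
        dataset.labels, dataset.prior, cfg, dataset.tf_on,
    )
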