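"""Prior-guided variational autoencoder for TF activity and GRN inference.

The generative model reconstructs each cell's expression vector x as
``x_hat = W . e_tf`` where ``e_tf`` is a non-negative per-cell transcription
factor activity vector produced by the decoder head (ReLU output) and ``W``
is an explicit, trainable TF x gene weight matrix initialized from a signed
prior network. Three schedules shape training:

* ``alpha`` blends the prior-driven ULM activity estimate with the decoder's
  data-driven estimate, ramping from prior toward data;
* the mask factor ``m(t)`` blends the weight matrix toward the prior early in
  training and releases it to the learned weights late (decreasing logistic);
* ``gamma`` linearly ramps an L1 sparsity penalty on ``W``.

All forward/backward passes are written directly in numpy so training is
lightweight and bit-reproducible for a fixed seed on a fixed thread count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._containers import AlignedDataset, ExpressionMatrix, PriorGRN

__all__ = [
    "ModelConfig",
    "LossReport",
    "TFActivityMatrix",
    "TFActivityVAE",
    "ulm_activities",
    "alpha_step",
    "gamma_schedule",
    "mask_factor",
    "blend_activities",
    "blend_grn",
    "grn_l1_loss",
    "train",
    "finetune_per_cluster",
    "infer_activities",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TFActivityMatrix:
    """Non-negative cells x TF activity matrix with identifiers."""

    values: np.ndarray
    cell_ids: np.ndarray
    tf_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("TF activities must be finite")
        if (self.values < 0).any():
            raise ValueError("TF activities must be non-negative")


@dataclass
class LossReport:
    """Loss components for one epoch (minimization convention, negative ELBO)."""

    reconstruction: float
    kl: float
    grn_l1: float

    @property
    def elbo(self) -> float:
        return self.reconstruction + self.kl

    @property
    def total(self) -> float:
        return self.elbo + self.grn_l1


@dataclass
class ModelConfig:
    """Hyperparameters for :class:`TFActivityVAE` (see class docstring)."""

    encoder_layer_sizes: tuple = (128,)
    decoder_layer_sizes: tuple = (64,)
    latent_dim: int = 32
    alpha_start: float = 0.0
    alpha_max: float = 0.9
    delta_alpha: float = 0.02
    gamma_max: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    finetune_lr_scale: float = 0.5
    finetune_epochs: int = 400
    min_cluster_size: int = 20
    val_fraction: float = 0.15
    lr_patience: int = 10
    lr_factor: float = 0.5
    mask_increasing: bool = False
    alpha_per_batch: bool = False

    def __post_init__(self) -> None:
        self.encoder_layer_sizes = tuple(self.encoder_layer_sizes)
        self.decoder_layer_sizes = tuple(self.decoder_layer_sizes)
        if not 1 <= len(self.encoder_layer_sizes) <= 3:
            raise ValueError("encoder_layer_sizes must have 1-3 layers")
        if not 1 <= len(self.decoder_layer_sizes) <= 2:
            raise ValueError("decoder_layer_sizes must have 1-2 layers")
        if not 0 <= self.alpha_start <= self.alpha_max <= 1:
            raise ValueError("need 0 <= alpha_start <= alpha_max <= 1")
        if self.gamma_max < 0:
            raise ValueError("gamma_max must be non-negative")


# ---------------------------------------------------------------------------
# schedules and pure arithmetic pieces


def alpha_step(alpha: float, delta_alpha: float, alpha_max: float) -> float:
    """One step of the prior-to-data blending schedule: min(alpha_max, alpha + delta)."""
    return min(alpha_max, alpha + delta_alpha)


def gamma_schedule(t: int, T: int, gamma_max: float) -> float:
    """Linear L1-penalty ramp: gamma_max * t / T."""
    if T == 0:
        raise ValueError("total epochs T must be positive")
    return gamma_max * (t / T)  # t/T first: endpoints are exact in float


def mask_factor(t: float, T: float, increasing: bool = False) -> float:
    """Logistic prior-retention factor, transitioning 1 -> 0 over training.

    ``m(t) = 1 / (1 + exp((t - T/2) / (T/20)))``; midpoint m(T/2) = 0.5.
    ``increasing=True`` selects the mirrored 0 -> 1 variant.
    """
    if T <= 0:
        raise ValueError("total epochs T must be positive")
    arg = (t - T / 2) / (T / 20)
    if increasing:
        arg = -arg
    return float(1.0 / (1.0 + np.exp(arg)))


def blend_activities(e_ulm: np.ndarray, e_dec: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination (1-alpha) * ULM estimate + alpha * decoder estimate."""
    return (1.0 - alpha) * np.asarray(e_ulm) + alpha * np.asarray(e_dec)


def blend_grn(w_prev: np.ndarray, w_prior: np.ndarray, m: float) -> np.ndarray:
    """Convex prior blend of the GRN weights: m * W_prior + (1-m) * W_prev."""
    return m * np.asarray(w_prior) + (1.0 - m) * np.asarray(w_prev)


def grn_l1_loss(w: np.ndarray, gamma: float) -> float:
    """Scheduled sparsity penalty gamma * sum |W|."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(gamma * np.abs(w).sum())


# ---------------------------------------------------------------------------
# ULM activity scoring


def ulm_activities(
    expr: ExpressionMatrix | np.ndarray,
    prior: PriorGRN,
    clip: bool = True,
) -> np.ndarray:
    """Per-cell univariate-linear-model TF activities (slope t-statistics).

    For each cell and TF, the cell's expression vector (over genes) is
    regressed on the TF's prior weight vector (with intercept); the activity
    is the t-statistic of the slope. Degenerate regressions (zero-variance
    regressor or response) score 0. With ``clip=True`` (the reporting/blending
    convention) negative scores are clipped to 0.
    """
    x = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    if x.ndim == 1:
        x = x[None, :]
    r = prior.dense().T  # genes x TFs
    n_genes = r.shape[0]
    if x.shape[1] != n_genes:
        raise ValueError(f"expression has {x.shape[1]} genes, prior has {n_genes}")
    if (np.abs(r).sum(axis=0) == 0).any():
        bad = prior.tf_ids[np.abs(r).sum(axis=0) == 0]
        raise ValueError(f"prior contains all-zero TF rows (should be filtered): {list(bad[:5])}")
    if n_genes < 3:
        raise ValueError("ULM needs at least 3 genes (df = n_genes - 2 > 0)")

    xc = x - x.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=0, keepdims=True)
    x_norm = np.linalg.norm(xc, axis=1)  # cells
    r_norm = np.linalg.norm(rc, axis=0)  # TFs
    denom = np.outer(x_norm, r_norm)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xc @ rc) / denom
    rho[~np.isfinite(rho)] = 0.0
    rho = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    df = n_genes - 2
    t = rho * np.sqrt(df / (1.0 - rho**2))
    if clip:
        t = np.maximum(t, 0.0)
    return t


# ---------------------------------------------------------------------------
# internal numerics: parameter store, Adam, forward/backward


def _init_params(n_genes: int, n_tfs: int, cfg: ModelConfig, w_prior: np.ndarray, rng) -> dict:
    """He-style initialization for the MLPs; W starts at the signed prior."""
    params: dict[str, np.ndarray] = {}

    def dense(name, fan_in, fan_out):
        params[f"{name}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"{name}_b"] = np.zeros(fan_out)

    prev = n_genes
    for i, h in enumerate(cfg.encoder_layer_sizes):
        dense(f"enc{i}", prev, h)
        prev = h
    dense("mu", prev, cfg.latent_dim)
    dense("lv", prev, cfg.latent_dim)
    prev = cfg.latent_dim
    for i, h in enumerate(cfg.decoder_layer_sizes):
        dense(f"dec{i}", prev, h)
        prev = h
    dense("tf", prev, n_tfs)
    params["grn_W"] = w_prior.astype(np.float64).copy()
    return params


class _Adam:
    """Plain Adam with a scalar learning-rate multiplier for plateau decay."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.scale = 1.0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * self.scale * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] = params[k] - lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


_LV_CLIP = 15.0  # log-variance clamp for numerical safety


def _forward(params: dict, cfg: ModelConfig, x: np.ndarray, e_ulm: np.ndarray | None,
             alpha: float, eps: np.ndarray | None, gamma: float):
    """Forward pass; returns losses and a cache for backprop."""
    cache: dict = {"x": x, "acts": []}
    h = x
    for i in range(len(cfg.encoder_layer_sizes)):
        a = h @ params[f"enc{i}_W"] + params[f"enc{i}_b"]
        cache["acts"].append((h, a))
        h = np.maximum(a, 0.0)
    cache["enc_top"] = h
    mu = h @ params["mu_W"] + params["mu_b"]
    lv = np.clip(h @ params["lv_W"] + params["lv_b"], -_LV_CLIP, _LV_CLIP)
    sigma = np.exp(0.5 * lv)
    z = mu if eps is None else mu + sigma * eps
    cache.update(mu=mu, lv=lv, sigma=sigma, eps=eps, z=z)

    hd = z
    cache["dec_acts"] = []
    for i in range(len(cfg.decoder_layer_sizes)):
        a = hd @ params[f"dec{i}_W"] + params[f"dec{i}_b"]
        cache["dec_acts"].append((hd, a))
        hd = np.maximum(a, 0.0)
    a_tf = hd @ params["tf_W"] + params["tf_b"]
    e_dec = np.maximum(a_tf, 0.0)
    cache.update(dec_top=hd, a_tf=a_tf, e_dec=e_dec)

    e_hat = e_dec if e_ulm is None else blend_activities(e_ulm, e_dec, alpha)
    x_hat = e_hat @ params["grn_W"]
    cache.update(e_hat=e_hat, x_hat=x_hat, alpha=alpha, gamma=gamma)

    B = x.shape[0]
    recon = float(np.sum((x - x_hat) ** 2) / B)
    kl = float(0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / B)
    l1 = grn_l1_loss(params["grn_W"], gamma)
    return LossReport(recon, kl, l1), cache


def _backward(params: dict, cfg: ModelConfig, cache: dict) -> dict:
    """Gradients of the total loss for every parameter in ``params``."""
    grads: dict[str, np.ndarray] = {}
    x, x_hat = cache["x"], cache["x_hat"]
    B = x.shape[0]

    d_xhat = 2.0 * (x_hat - x) / B
    grads["grn_W"] = cache["e_hat"].T @ d_xhat + cache["gamma"] * np.sign(params["grn_W"])
    d_ehat = d_xhat @ params["grn_W"].T
    d_edec = cache["alpha"] * d_ehat if cache["alpha"] != 1.0 else d_ehat
    d_atf = d_edec * (cache["a_tf"] > 0)
    grads["tf_W"] = cache["dec_top"].T @ d_atf
    grads["tf_b"] = d_atf.sum(axis=0)
    d_h = d_atf @ params["tf_W"].T
    for i in reversed(range(len(cfg.decoder_layer_sizes))):
        h_in, a = cache["dec_acts"][i]
        d_a = d_h * (a > 0)
        grads[f"dec{i}_W"] = h_in.T @ d_a
        grads[f"dec{i}_b"] = d_a.sum(axis=0)
        d_h = d_a @ params[f"dec{i}_W"].T
    dz = d_h

    mu, lv, sigma, eps = cache["mu"], cache["lv"], cache["sigma"], cache["eps"]
    d_mu = dz + mu / B
    d_lv = 0.5 * (np.exp(lv) - 1.0) / B
    if eps is not None:
        d_lv = d_lv + dz * eps * 0.5 * sigma
    h_top = cache["enc_top"]
    grads["mu_W"] = h_top.T @ d_mu
    grads["mu_b"] = d_mu.sum(axis=0)
    grads["lv_W"] = h_top.T @ d_lv
    grads["lv_b"] = d_lv.sum(axis=0)
    d_h = d_mu @ params["mu_W"].T + d_lv @ params["lv_W"].T
    for i in reversed(range(len(cfg.encoder_layer_sizes))):
        h_in, a = cache["acts"][i]
        d_a = d_h * (a > 0)
        grads[f"enc{i}_W"] = h_in.T @ d_a
        grads[f"enc{i}_b"] = d_a.sum(axis=0)
        d_h = d_a @ params[f"enc{i}_W"].T
    return grads


# ---------------------------------------------------------------------------
# the estimator


class TFActivityVAE(TransformerMixin, BaseEstimator):
    """Prior-guided VAE inferring per-cell TF activities and a weighted GRN.

    Parameters mirror :class:`ModelConfig`. After :meth:`fit`:

    Attributes
    ----------
    grn_weights_ : ndarray (n_tfs, n_genes)
        The learned weighted regulatory network W.
    history_ : list of LossReport
        Per-epoch training loss components.
    val_history_ : list of float
        Per-epoch validation total loss.
    alpha_ : float
        Final value of the prior-to-data blending coefficient.
    prior_ : PriorGRN
        The (aligned) prior used for initialization and ULM scoring.
    """

    def __init__(self, encoder_layer_sizes=(128,), decoder_layer_sizes=(64,),
                 latent_dim=32, alpha_start=0.0, alpha_max=0.9, delta_alpha=0.02,
                 gamma_max=1e-3, epochs=100, batch_size=128, learning_rate=1e-3,
                 seed=0, finetune_lr_scale=0.5, finetune_epochs=400,
                 min_cluster_size=20, val_fraction=0.15, lr_patience=10,
                 lr_factor=0.5, mask_increasing=False, alpha_per_batch=False):
        self.encoder_layer_sizes = encoder_layer_sizes
        self.decoder_layer_sizes = decoder_layer_sizes
        self.latent_dim = latent_dim
        self.alpha_start = alpha_start
        self.alpha_max = alpha_max
        self.delta_alpha = delta_alpha
        self.gamma_max = gamma_max
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.finetune_lr_scale = finetune_lr_scale
        self.finetune_epochs = finetune_epochs
        self.min_cluster_size = min_cluster_size
        self.val_fraction = val_fraction
        self.lr_patience = lr_patience
        self.lr_factor = lr_factor
        self.mask_increasing = mask_increasing
        self.alpha_per_batch = alpha_per_batch

    # -- config plumbing ----------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in ModelConfig.__dataclass_fields__})

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "TFActivityVAE":
        return cls(**asdict(cfg))

    # -- public API ---------------------------------------------------------

    def fit(self, data: AlignedDataset, y=None) -> "TFActivityVAE":
        """Train on an aligned dataset (split is created if absent)."""
        cfg = self._config()
        if data.train_index.size == 0:
            from .io import split_train_val

            data = split_train_val(data, cfg.val_fraction, cfg.seed)
        self._fit_core(data, cfg)
        return self

    def _fit_core(self, data: AlignedDataset, cfg: ModelConfig,
                  init_params: dict | None = None, alpha_fixed: float | None = None,
                  mask_fixed: float | None = None, gamma_fixed: float | None = None,
                  epochs: int | None = None, lr: float | None = None) -> None:
        x = data.expression.values
        w_prior = data.prior.dense()
        rng = np.random.default_rng(cfg.seed)
        params = (
            {k: v.copy() for k, v in init_params.items()}
            if init_params is not None
            else _init_params(data.n_genes, data.n_tfs, cfg, w_prior, rng)
        )
        T = cfg.epochs if epochs is None else epochs
        opt = _Adam(params, cfg.learning_rate if lr is None else lr)

        ulm_raw = ulm_activities(data.expression, data.prior, clip=False)
        ulm = np.maximum(ulm_raw, 0.0)
        train_idx, val_idx = data.train_index, data.val_index
        alpha = cfg.alpha_start if alpha_fixed is None else alpha_fixed

        history: list[LossReport] = []
        val_history: list[float] = []
        alpha_history: list[float] = []
        best_val, stale = np.inf, 0
        for t in range(1, T + 1):
            alpha_history.append(alpha)
            gamma = gamma_schedule(t, T, cfg.gamma_max) if gamma_fixed is None else gamma_fixed
            order = rng.permutation(train_idx)
            recon_s = kl_s = 0.0
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = x[idx]
                eps = rng.standard_normal((len(idx), cfg.latent_dim))
                report, cache = _forward(params, cfg, xb, ulm[idx], alpha, eps, gamma)
                if not np.isfinite(report.total):
                    raise FloatingPointError(f"non-finite training loss at epoch {t}")
                grads = _backward(params, cfg, cache)
                opt.step(params, grads)
                recon_s += report.reconstruction
                kl_s += report.kl
                n_batches += 1
                if cfg.alpha_per_batch and alpha_fixed is None:
                    alpha = alpha_step(alpha, cfg.delta_alpha, cfg.alpha_max)

            # prior blend of W, once per epoch after the optimizer steps
            m = mask_factor(t, T, cfg.mask_increasing) if mask_fixed is None else mask_fixed
            params["grn_W"] = blend_grn(params["grn_W"], w_prior, m)

            history.append(
                LossReport(recon_s / n_batches, kl_s / n_batches,
                           grn_l1_loss(params["grn_W"], gamma))
            )
            if val_idx.size:
                vrep, _ = _forward(params, cfg, x[val_idx], ulm[val_idx], alpha, None, gamma)
                vtot = vrep.total
            else:
                vtot = history[-1].total
            if not np.isfinite(vtot):
                raise FloatingPointError(f"non-finite validation loss at epoch {t}")
            val_history.append(vtot)
            if vtot < best_val - 1e-12:
                best_val, stale = vtot, 0
            else:
                stale += 1
                if stale >= cfg.lr_patience:
                    opt.scale *= cfg.lr_factor
                    stale = 0

            if not cfg.alpha_per_batch and alpha_fixed is None:
                alpha = alpha_step(alpha, cfg.delta_alpha, cfg.alpha_max)

        self.params_ = params
        self.grn_weights_ = params["grn_W"]
        self.prior_ = data.prior
        self.gene_ids_ = data.expression.gene_ids
        self.tf_ids_ = data.prior.tf_ids
        self.alpha_ = alpha
        self.alpha_history_ = alpha_history
        self.history_ = history
        self.val_history_ = val_history
        self.n_epochs_ = T

    # -- forward-pass pieces (eval mode) ------------------------------------

    def encode(self, x: np.ndarray):
        """Map expression vectors to the latent posterior (mu, sigma)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if not np.isfinite(x).all():
            raise ValueError("non-finite encoder input")
        cfg = self._config()
        h = x
        for i in range(len(cfg.encoder_layer_sizes)):
            h = np.maximum(h @ self.params_[f"enc{i}_W"] + self.params_[f"enc{i}_b"], 0.0)
        mu = h @ self.params_["mu_W"] + self.params_["mu_b"]
        lv = np.clip(h @ self.params_["lv_W"] + self.params_["lv_b"], -_LV_CLIP, _LV_CLIP)
        return mu, np.exp(0.5 * lv)

    @staticmethod
    def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
        """z = mu + sigma * eps."""
        return np.asarray(mu) + np.asarray(sigma) * np.asarray(eps)

    def decode_tf(self, z: np.ndarray) -> np.ndarray:
        """Decoder head: latent z -> non-negative TF activities."""
        h = np.atleast_2d(np.asarray(z, dtype=np.float64))
        cfg = self._config()
        for i in range(len(cfg.decoder_layer_sizes)):
            h = np.maximum(h @ self.params_[f"dec{i}_W"] + self.params_[f"dec{i}_b"], 0.0)
        return np.maximum(h @ self.params_["tf_W"] + self.params_["tf_b"], 0.0)

    def reconstruct(self, e_tf: np.ndarray) -> np.ndarray:
        """Linear GRN output layer: x_hat = e_tf . W (no bias, no nonlinearity)."""
        e_tf = np.atleast_2d(np.asarray(e_tf, dtype=np.float64))
        if e_tf.shape[1] != self.grn_weights_.shape[0]:
            raise ValueError(
                f"activity vector has {e_tf.shape[1]} TFs, W expects {self.grn_weights_.shape[0]}"
            )
        return e_tf @ self.grn_weights_

    def transform(self, expr: ExpressionMatrix) -> TFActivityMatrix:
        """Infer per-cell TF activities (eval mode, z = mu, no sampling)."""
        if not np.array_equal(expr.gene_ids, self.gene_ids_):
            raise ValueError("gene identifiers/order differ from the fitted model")
        mu, _ = self.encode(expr.values)
        e_dec = self.decode_tf(mu)
        e_ulm = ulm_activities(expr, self.prior_, clip=True)
        vals = blend_activities(e_ulm, e_dec, self.alpha_)
        return TFActivityMatrix(vals, expr.cell_ids, self.tf_ids_)

    # -- per-cluster fine-tuning --------------------------------------------

    def finetune_per_cluster(self, data: AlignedDataset, labels) -> dict:
        """Continue training per cell cluster, from the fitted global model.

        Each cluster's model copies the global parameters and trains on that
        cluster's cells only, at ``learning_rate * finetune_lr_scale``, with
        alpha held at its final value and the prior mask held constant at its
        terminal (near-zero) value so adaptation is purely data-driven.

        Returns ``{cluster: (model, W, TFActivityMatrix)}``.
        """
        cfg = self._config()
        labels = _as_label_array(labels, data.expression.cell_ids)
        out: dict = {}
        m_final = mask_factor(self.n_epochs_, self.n_epochs_, cfg.mask_increasing)
        for cluster in sorted(map(str, np.unique(labels))):
            idx = np.flatnonzero(labels.astype(str) == cluster)
            if idx.size < cfg.min_cluster_size:
                warnings.warn(
                    f"cluster {cluster!r} has {idx.size} cells "
                    f"(< {cfg.min_cluster_size}); skipped"
                )
                continue
            sub_expr = data.expression.subset(cell_idx=idx)
            sub = AlignedDataset(sub_expr, data.prior)
            from .io import split_train_val

            sub = split_train_val(sub, cfg.val_fraction, cfg.seed)
            clone = TFActivityVAE.from_config(cfg)
            clone._fit_core(
                sub, cfg, init_params=self.params_, alpha_fixed=self.alpha_,
                mask_fixed=m_final, gamma_fixed=cfg.gamma_max,
                epochs=cfg.finetune_epochs,
                lr=cfg.learning_rate * cfg.finetune_lr_scale,
            )
            out[cluster] = (clone, clone.grn_weights_, clone.transform(sub_expr))
        return out


def _as_label_array(labels, cell_ids: np.ndarray) -> np.ndarray:
    """Accept a dict/Series/array of per-cell labels; align to cell order."""
    import pandas as pd

    if isinstance(labels, Mapping):
        missing = [c for c in cell_ids if c not in labels]
        if missing:
            raise ValueError(f"unlabeled cells: {missing[:5]}")
        return np.array([labels[c] for c in cell_ids], dtype=object)
    if isinstance(labels, pd.Series):
        if not set(cell_ids) <= set(labels.index):
            raise ValueError("label Series does not cover all cells")
        return labels.loc[list(cell_ids)].to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != len(cell_ids):
        raise ValueError("label array length differs from number of cells")
    return labels


# ---------------------------------------------------------------------------
# thin functional wrappers


def train(data: AlignedDataset, config: ModelConfig):
    """Fit a :class:`TFActivityVAE`; returns (model, per-epoch loss history)."""
    model = TFActivityVAE.from_config(config).fit(data)
    return model, model.history_


def finetune_per_cluster(model: TFActivityVAE, data: AlignedDataset, labels, config=None):
    if config is not None:
        model = _with_config(model, config)
    return model.finetune_per_cluster(data, labels)


def infer_activities(model: TFActivityVAE, expr: ExpressionMatrix) -> TFActivityMatrix:
    return model.transform(expr)


def _with_config(model: TFActivityVAE, config: ModelConfig) -> TFActivityVAE:
    clone = TFActivityVAE.from_config(config)
    for attr in ("params_", "grn_weights_", "prior_", "gene_ids_", "tf_ids_",
                 "alpha_", "alpha_history_", "history_", "val_history_", "n_epochs_"):
        setattr(clone, attr, getattr(model, attr))
    return clone
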