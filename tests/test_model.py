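import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

import grnvae as g
from grnvae.model import _backward, _forward, _init_params


# ---------------------------------------------------------------------------
# schedules


@pytest.mark.parametrize(
    "a,da,amax,expected",
    [(0.2, 0.1, 0.5, 0.3), (0.45, 0.1, 0.5, 0.5), (0.3, 0.0, 0.5, 0.3)],
)
def test_alpha_step(a, da, amax, expected):
    assert g.alpha_step(a, da, amax) == pytest.approx(expected)


def test_gamma_schedule_endpoints_and_midpoint():
    assert g.gamma_schedule(0, 40, 2.0) == 0.0
    assert g.gamma_schedule(40, 40, 2.0) == 2.0
    assert g.gamma_schedule(20, 40, 2.0) == 1.0
    with pytest.raises(ValueError):
        g.gamma_schedule(0, 0, 1.0)


def test_mask_factor_is_decreasing_logistic():
    T = 100
    assert g.mask_factor(T / 2, T) == pytest.approx(0.5)
    assert g.mask_factor(0, T) == pytest.approx(1 / (1 + np.exp(-10)))
    assert g.mask_factor(T, T) == pytest.approx(1 / (1 + np.exp(10)))
    vals = [g.mask_factor(t, T) for t in range(T + 1)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    # mirrored variant increases
    up = [g.mask_factor(t, T, increasing=True) for t in range(T + 1)]
    assert all(a < b for a, b in zip(up, up[1:]))


# ---------------------------------------------------------------------------
# arithmetic pieces


def test_blend_activities_endpoints_and_midpoint():
    ulm, dec = np.array([2.0, 0.0]), np.array([0.0, 2.0])
    assert np.array_equal(g.blend_activities(ulm, dec, 0.0), ulm)
    assert np.array_equal(g.blend_activities(ulm, dec, 1.0), dec)
    assert np.array_equal(g.blend_activities(ulm, dec, 0.5), [1.0, 1.0])


def test_blend_grn_and_support_union():
    prev, prior = np.array([[2.0]]), np.array([[1.0]])
    assert g.blend_grn(prev, prior, 1.0) == prior
    assert g.blend_grn(prev, prior, 0.0) == prev
    assert g.blend_grn(prev, prior, 0.25) == pytest.approx(1.75)
    rng = np.random.default_rng(0)
    a = rng.normal(size=(4, 6)) * (rng.uniform(size=(4, 6)) < 0.3)
    b = rng.normal(size=(4, 6)) * (rng.uniform(size=(4, 6)) < 0.3)
    blended = g.blend_grn(a, b, 0.37)
    assert set(zip(*np.nonzero(blended))) <= (
        set(zip(*np.nonzero(a))) | set(zip(*np.nonzero(b)))
    )


@given(st.floats(0.1, 10.0))
def test_grn_l1_loss_homogeneity(scale):
    w = np.array([[1.0, -2.0], [0.0, 3.0]])
    assert g.grn_l1_loss(w, 0.5) == pytest.approx(3.0)
    assert g.grn_l1_loss(w, 0.0) == 0.0
    assert g.grn_l1_loss(scale * w, 1.0) == pytest.approx(scale * g.grn_l1_loss(w, 1.0))


# ---------------------------------------------------------------------------
# ULM


def ulm_oracle(x, r):
    """Independent per-cell, per-TF least-squares t-statistic (with intercept)."""
    n = len(r)
    X = np.column_stack([np.ones(n), r])
    beta, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    df = n - 2
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[1] / np.sqrt(cov[1, 1])


def test_ulm_matches_least_squares_oracle():
    rng = np.random.default_rng(3)
    n_cells, n_genes, n_tfs = 20, 50, 5
    x = rng.uniform(0, 5, size=(n_cells, n_genes))
    w = (rng.uniform(size=(n_tfs, n_genes)) < 0.3) * np.where(
        rng.uniform(size=(n_tfs, n_genes)) < 0.5, 1.0, -1.0
    )
    w[np.abs(w).sum(axis=1) == 0, 0] = 1.0
    prior = g.PriorGRN(
        np.array([f"T{i}" for i in range(n_tfs)], dtype=object),
        np.array([f"g{j}" for j in range(n_genes)], dtype=object),
        sp.csr_matrix(w),
    )
    got = g.ulm_activities(x, prior, clip=False)
    expected = np.array(
        [[ulm_oracle(x[c], w[i]) for i in range(n_tfs)] for c in range(n_cells)]
    )
    np.testing.assert_allclose(got, expected, rtol=1e-8)


def test_ulm_proportional_cell_scores_own_tf_highest(tiny_prior):
    rng = np.random.default_rng(0)
    w = np.zeros((3, 40))
    w[0, :10] = 1.0
    w[1, 10:20] = 1.0
    w[2, 20:30] = 1.0
    prior = g.PriorGRN(
        np.array(["T0", "T1", "T2"], dtype=object),
        np.array([f"g{j}" for j in range(40)], dtype=object),
        sp.csr_matrix(w),
    )
    x = 3.0 * w[1] + rng.normal(0, 1e-3, size=40)
    acts = g.ulm_activities(x[None, :], prior, clip=False)
    assert acts[0].argmax() == 1


def test_ulm_degenerate_and_error_cases():
    w = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 0.0, 0.0, 0.0]])
    prior = g.PriorGRN(
        np.array(["T0", "T1"], dtype=object),
        np.array([f"g{j}" for j in range(4)], dtype=object),
        sp.csr_matrix(w),
    )
    # T0's regressor is constant -> zero variance -> activity 0
    acts = g.ulm_activities(np.array([[1.0, 2.0, 3.0, 4.0]]), prior, clip=False)
    assert acts[0, 0] == 0.0
    # expression orthogonal to the (centered) regressor -> activity 0
    r = w[1] - w[1].mean()
    x = np.array([1.0, 1.0, 1.0, 1.0]) + 0 * r
    assert g.ulm_activities(x[None, :], prior, clip=False)[0, 1] == 0.0
    # identical cells give identical rows
    x2 = np.array([[1.0, 2.0, 0.0, 4.0]] * 2)
    a2 = g.ulm_activities(x2, prior)
    assert np.array_equal(a2[0], a2[1])
    # all-zero prior row is a contract violation
    w0 = w.copy()
    w0[1] = 0.0
    bad = g.PriorGRN(prior.tf_ids, prior.gene_ids, sp.csr_matrix(w0))
    with pytest.raises(ValueError, match="all-zero"):
        g.ulm_activities(x2, bad)


# ---------------------------------------------------------------------------
# forward / backward correctness


def test_backward_matches_finite_differences():
    cfg = g.ModelConfig(encoder_layer_sizes=(7,), decoder_layer_sizes=(6,),
                        latent_dim=4, epochs=1)
    rng = np.random.default_rng(0)
    n_genes, n_tfs, B = 9, 3, 5
    w_prior = rng.normal(size=(n_tfs, n_genes))
    params = _init_params(n_genes, n_tfs, cfg, w_prior, rng)
    x = rng.uniform(0, 2, size=(B, n_genes))
    ulm = rng.uniform(0, 2, size=(B, n_tfs))
    eps = rng.standard_normal((B, cfg.latent_dim))
    alpha, gamma = 0.6, 0.01

    _, cache = _forward(params, cfg, x, ulm, alpha, eps, gamma)
    grads = _backward(params, cfg, cache)

    h = 1e-6
    for name in grads:
        p = params[name]
        flat_idx = [0, p.size // 2, p.size - 1] if p.size > 2 else range(p.size)
        for k in flat_idx:
            orig = p.flat[k]
            p.flat[k] = orig + h
            lp, _ = _forward(params, cfg, x, ulm, alpha, eps, gamma)
            p.flat[k] = orig - h
            lm, _ = _forward(params, cfg, x, ulm, alpha, eps, gamma)
            p.flat[k] = orig
            num = (lp.total - lm.total) / (2 * h)
            assert grads[name].flat[k] == pytest.approx(num, rel=1e-4, abs=1e-6), name


def test_reparameterize_arithmetic():
    assert np.array_equal(g.TFActivityVAE.reparameterize([1.0, 2.0], [1.0, 1.0], [-1.0, 1.0]),
                          [0.0, 3.0])
    assert np.array_equal(g.TFActivityVAE.reparameterize([1.0, 2.0], [0.0, 0.0], [5.0, -5.0]),
                          [1.0, 2.0])


def test_encode_decode_contracts(model_default, aligned_default):
    x = aligned_default.expression.values[:3]
    mu, sigma = model_default.encode(x)
    assert (sigma > 0).all()
    mu2, sigma2 = model_default.encode(x)
    assert np.array_equal(mu, mu2) and np.array_equal(sigma, sigma2)
    mu0, sigma0 = model_default.encode(np.zeros(aligned_default.n_genes))
    assert np.isfinite(mu0).all() and np.isfinite(sigma0).all()
    with pytest.raises(ValueError):
        model_default.encode(np.full(aligned_default.n_genes, np.nan))
    z = np.random.default_rng(0).normal(size=(4, mu.shape[1]))
    e = model_default.decode_tf(z)
    assert (e >= 0).all()
    assert np.array_equal(e, model_default.decode_tf(z))


def test_reconstruct_is_linear_grn_product(model_default):
    n_tfs, n_genes = model_default.grn_weights_.shape
    e = np.zeros(n_tfs)
    assert np.array_equal(model_default.reconstruct(e), np.zeros((1, n_genes)))
    e = np.random.default_rng(1).uniform(size=n_tfs)
    assert np.allclose(model_default.reconstruct(e), e @ model_default.grn_weights_)
    with pytest.raises(ValueError):
        model_default.reconstruct(np.ones(n_tfs + 1))


def test_reconstruct_identity_weight_matrix():
    model = g.TFActivityVAE()
    model.grn_weights_ = np.array([[1.0, -1.0], [0.0, 2.0]])
    assert np.array_equal(model.reconstruct([1.0, 1.0]), [[1.0, 1.0]])
    model.grn_weights_ = np.eye(3)
    e = np.array([0.3, 0.0, 2.0])
    assert np.array_equal(model.reconstruct(e)[0], e)


# ---------------------------------------------------------------------------
# training behaviour


def test_training_reduces_validation_loss(model_default):
    assert model_default.val_history_[-1] < model_default.val_history_[0]


def test_alpha_history_matches_closed_form(model_default):
    cfg = model_default._config()
    expected = [
        min(cfg.alpha_max, cfg.alpha_start + t * cfg.delta_alpha)
        for t in range(model_default.n_epochs_)
    ]
    assert model_default.alpha_history_ == pytest.approx(expected)


def test_training_is_deterministic(aligned_default):
    cfg = g.ModelConfig(epochs=8, seed=123)
    m1, h1 = g.train(aligned_default, cfg)
    m2, h2 = g.train(aligned_default, cfg)
    assert [r.total for r in h1] == [r.total for r in h2]
    assert np.array_equal(m1.grn_weights_, m2.grn_weights_)


def test_loss_accounting_identity(model_default):
    for rep in model_default.history_:
        assert rep.total == pytest.approx(rep.reconstruction + rep.kl + rep.grn_l1)
        assert rep.elbo == pytest.approx(rep.reconstruction + rep.kl)


def test_kl_closed_form_identities():
    # encoder forced to mu=0, logvar=0 -> KL = 0
    cfg = g.ModelConfig(encoder_layer_sizes=(4,), decoder_layer_sizes=(4,),
                        latent_dim=2, epochs=1)
    rng = np.random.default_rng(0)
    params = _init_params(5, 2, cfg, np.zeros((2, 5)), rng)
    for k in ("mu_W", "mu_b", "lv_W", "lv_b"):
        params[k][...] = 0.0
    x = rng.uniform(size=(3, 5))
    rep, _ = _forward(params, cfg, x, np.zeros((3, 2)), 0.5, None, 0.0)
    assert rep.kl == pytest.approx(0.0)
    # mu=(1,), sigma=(1,) -> KL = 0.5 per cell: shift the mu bias
    cfg1 = g.ModelConfig(encoder_layer_sizes=(4,), decoder_layer_sizes=(4,),
                         latent_dim=1, epochs=1)
    params = _init_params(5, 2, cfg1, np.zeros((2, 5)), rng)
    for k in ("mu_W", "lv_W", "lv_b"):
        params[k][...] = 0.0
    params["mu_b"][...] = 1.0
    rep, _ = _forward(params, cfg1, x, np.zeros((3, 2)), 0.5, None, 0.0)
    assert rep.kl == pytest.approx(0.5)


def test_perfect_reconstruction_zero_loss():
    cfg = g.ModelConfig(encoder_layer_sizes=(4,), decoder_layer_sizes=(4,),
                        latent_dim=2, epochs=1)
    rng = np.random.default_rng(0)
    params = _init_params(3, 2, cfg, np.eye(2, 3), rng)
    ulm = np.array([[1.0, 2.0], [0.5, 0.0]])
    x = ulm @ params["grn_W"]
    rep, _ = _forward(params, cfg, x, ulm, 0.0, None, 0.0)  # alpha=0: e_hat = ulm
    assert rep.reconstruction == pytest.approx(0.0)


def test_untrained_alpha_zero_reduces_to_ulm(aligned_default):
    cfg = g.ModelConfig(epochs=0, alpha_start=0.0, alpha_max=0.0, seed=0)
    model, hist = g.train(aligned_default, cfg)
    assert hist == []
    acts = model.transform(aligned_default.expression)
    expected = np.maximum(
        g.ulm_activities(aligned_default.expression, aligned_default.prior, clip=False), 0.0
    )
    np.testing.assert_allclose(acts.values, expected, rtol=1e-12)


def test_infer_activities_contracts(model_default, aligned_default):
    acts = model_default.transform(aligned_default.expression)
    assert (acts.values >= 0).all()
    acts2 = g.infer_activities(model_default, aligned_default.expression)
    assert np.array_equal(acts.values, acts2.values)
    wrong = aligned_default.expression.subset(gene_idx=np.arange(aligned_default.n_genes - 1))
    with pytest.raises(ValueError, match="gene"):
        model_default.transform(wrong)


def test_cluster_marker_tf_has_higher_activity(model_default, aligned_default, sim_default):
    # simulator guarantees TF000 is on only in cluster c0
    acts = model_default.transform(aligned_default.expression)
    labels = sim_default.labels
    j = int(np.flatnonzero(acts.tf_ids == "TF000")[0])
    in_c0 = acts.values[labels == "c0", j].mean()
    elsewhere = acts.values[labels != "c0", j].mean()
    assert in_c0 > elsewhere


# ---------------------------------------------------------------------------
# fine-tuning


def test_zero_finetune_epochs_keeps_global_weights(model_default, aligned_default, sim_default):
    model = g.TFActivityVAE.from_config(model_default._config())
    for attr in ("params_", "grn_weights_", "prior_", "gene_ids_", "tf_ids_",
                 "alpha_", "alpha_history_", "history_", "val_history_", "n_epochs_"):
        setattr(model, attr, getattr(model_default, attr))
    model.finetune_epochs = 0
    res = model.finetune_per_cluster(aligned_default, sim_default.labels)
    for _, w, _ in res.values():
        assert np.array_equal(w, model_default.grn_weights_)


def test_small_clusters_skipped_with_warning(model_default, aligned_default):
    labels = np.array(["big"] * (aligned_default.n_cells - 3) + ["tiny"] * 3, dtype=object)
    model = g.TFActivityVAE.from_config(model_default._config())
    for attr in ("params_", "grn_weights_", "prior_", "gene_ids_", "tf_ids_",
                 "alpha_", "alpha_history_", "history_", "val_history_", "n_epochs_"):
        setattr(model, attr, getattr(model_default, attr))
    model.finetune_epochs = 1
    with pytest.warns(UserWarning, match="tiny"):
        res = model.finetune_per_cluster(aligned_default, labels)
    assert set(res) == {"big"}


def test_sklearn_param_interface():
    est = g.TFActivityVAE(latent_dim=8)
    assert est.get_params()["latent_dim"] == 8
    est.set_params(epochs=5)
    assert est._config().epochs == 5
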