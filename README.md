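# grnvae

Prior-guided variational inference of per-cell transcription-factor (TF)
activities and weighted gene regulatory networks (GRNs) from single-cell
expression data.

## Who this is for

Single-cell transcriptomics gives gene-level readouts, but many questions are
regulatory: *which TFs drive this cell state, and through which targets?*
`grnvae` answers both at once. It is aimed at computational biologists who
have a (log-normalized) cells × genes matrix and a curated signed TF–target
prior (e.g. a CollecTRI-style edge list) and want per-cell TF activities for
clustering and differential analysis, plus a weighted — optionally
cell-type-specific — GRN for mechanistic interpretation.

## The model

A variational autoencoder whose decoder ends in an explicit, trainable
TF × gene weight matrix **W**:

```
μ, σ = q_φ(z | x)            encoder (1–3 ReLU layers)
z    = μ + σ ⊙ ε,  ε ~ N(0, I)
ê    = p_θ(e | z)            decoder head, ReLU ⇒ ê ≥ 0 (TF activities)
x̂    = Wᵀ ê                  linear GRN read-out, no bias
```

**W** is initialized from the signed prior (±1 entries) and remains a
first-class output: its sign encodes activation/repression, its magnitude
regulatory strength. Three schedules steer training over epochs *t* = 1…*T*:

* **α-blending** — the activity used for reconstruction is
  `(1 − α)·e_ULM + α·ê`, where `e_ULM` is a univariate-linear-model estimate
  (per-cell regression of expression on each TF's prior target vector; the
  slope *t*-statistic, clipped at 0). α ramps `α(t+1) = min(α_max, α(t) + Δα)`
  from prior-driven to data-driven inference.
* **mask blending** — after each epoch, `W ← m(t)·W_prior + (1 − m(t))·W`
  with the decreasing logistic `m(t) = 1 / (1 + exp((t − T/2)/(T/20)))`, so
  early training respects the prior and late training trusts the data.
* **γ-scheduled sparsity** — an L1 penalty `γ(t)·Σ|W|` with `γ(t) = γ_max·t/T`
  prunes weak edges as training progresses.

The loss is the (negative) ELBO — Gaussian reconstruction error plus the KL
divergence of the latent posterior from N(0, I) — plus the L1 term, minimized
with Adam and a validation-plateau learning-rate decay on an 85–15 split.
After global training, per-cluster fine-tuning restarts from the global
parameters on each cluster's cells to produce cell-type-specific GRNs.

Everything (forward, backward, Adam) is implemented directly in numpy; runs
are bit-reproducible for a fixed seed and fast at typical desk scales
(hundreds of epochs on thousands of cells in seconds on one CPU).

## Worked example

```python
import grnvae as g

# synthetic data with known regulators (600 cells, 200 genes, 15 TFs)
ds = g.simulate(g.SimulationConfig(seed=0))
data = g.split_train_val(g.filter_and_align(ds.expression, ds.prior), seed=0)
model = g.TFActivityVAE(epochs=100, seed=0).fit(data)

acts = model.transform(data.expression)               # cells × TF activities
table = g.differential_tf_activity(acts, ds.labels)   # rank-sum + BH per group
print(table.head(3).to_string(index=False))
auroc, auprc = g.grn_auroc_auprc(
    model.grn_weights_, ds.truth_grn,
    pred_tf_ids=model.tf_ids_, pred_gene_ids=model.gene_ids_,
)
print(f"GRN recovery: AUROC {auroc:.3f} AUPRC {auprc:.3f}")
```

prints

```
   tf group      lfc        p_raw        p_adj  rank
TF000    c0 2.661381 4.940215e-88 3.580138e-87     1
TF004    c0 1.216271 6.188151e-83 1.160278e-82     2
TF014    c0 1.171354 4.331421e-49 5.906483e-49     3
GRN recovery: AUROC 1.000 AUPRC 1.000
```

`TF000` is, by simulator construction, exclusively active in cluster `c0`, and
it tops that cluster's differential table with a log2 fold change of 2.66 at
a vanishing adjusted P-value; with an uncorrupted prior the learned |W|
ranks every true edge above every non-edge (AUROC = AUPRC = 1).

The same pipeline is available from the shell:

```bash
grnvae simulate --out sim --seed 0
grnvae prepare  --expr sim/expression.tsv --prior sim/prior.tsv --out prep --seed 0
grnvae train    --data prep --out fit
grnvae finetune --data prep --model-dir fit --labels sim/labels.tsv --out ft
grnvae analyze diff --acts fit/activities.tsv --labels sim/labels.tsv --out diff.tsv
grnvae benchmark grn --pred fit/grn_weights.tsv --truth sim/truth_grn_all.tsv
```

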