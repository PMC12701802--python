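# Methods

## Model

`grnvae` infers per-cell transcription-factor activities and a weighted gene
regulatory network jointly, by embedding the network in the decoder of a
variational autoencoder. For a cell with (log-normalized) expression vector
`x ∈ R^G`:

- the encoder `q_φ(z|x)` (1–3 fully connected ReLU layers, then linear μ and
  log-variance heads) parameterizes a diagonal Gaussian posterior over a
  latent `z ∈ R^L`; sampling uses the reparameterization `z = μ + σ ⊙ ε`;
- the decoder `p_θ(e|z)` (1–2 ReLU layers plus a ReLU output head) maps `z`
  to a non-negative TF-activity vector `ê ∈ R^K_{≥0}`;
- the final layer is linear with no bias: `x̂ = Wᵀ ê`, where `W ∈ R^{K×G}` is
  the weighted GRN, initialized from the signed prior network (ternary
  entries as ±1, binary as +1).

Interpreting `ê` as activity requires the non-negativity (higher = stronger
regulatory influence in that cell); sign and strength of regulation live in
`W`. The decoder's "1–2 layers" count hidden layers before the TF head; the
GRN read-out layer is additional.

### Losses

Minimized objective per batch (minimization convention, i.e. negative ELBO):

- reconstruction: squared error summed over genes, averaged over the batch —
  a Gaussian likelihood, appropriate for log-normalized input (a count
  likelihood is out of scope);
- KL to the standard normal prior: `½ Σ_d (μ² + σ² − 1 − log σ²)`, averaged
  over the batch;
- GRN sparsity: `γ(t) Σ |W|`.

`total = reconstruction + kl + grn_l1` holds at every logged epoch by
construction, and is asserted in the tests.

### Schedules

Three scalar schedules over epochs `t = 1…T`:

- `α(t+1) = min(α_max, α(t) + Δα)` blends the reconstruction-side activity
  `(1−α)·e_ULM + α·ê` from a prior-driven estimate toward the decoder.
  The ULM estimate regresses, per cell, expression across genes on the TF's
  prior column (with intercept); the slope *t*-statistic is the activity,
  computed in closed form via the correlation identity
  `t = ρ √((G−2)/(1−ρ²))`, with degenerate regressions scoring 0, and is
  ReLU-clipped wherever the non-negativity convention applies (blending and
  reported activities; raw values are available with `clip=False`). ULM
  activities do not depend on model parameters and are precomputed once.
  α advances once per epoch (batch-level stepping is available via
  `alpha_per_batch`); defaults α_start = 0, α_max = 0.9, Δα = 0.02.
- the mask factor `m(t) = 1/(1 + exp((t − T/2)/(T/20)))` decreases 1 → 0 with
  midpoint exactly ½ at `t = T/2`; after each epoch's optimizer steps,
  `W ← m·W_prior + (1−m)·W`. Early training therefore pins W to the prior,
  late training releases it. The mirrored increasing variant is available
  behind `mask_increasing=True` for ablation.
- `γ(t) = γ_max · t/T` ramps the L1 penalty linearly from 0 so the prior
  structure establishes itself before sparsification bites; γ_max defaults
  to 1e-3.

### Optimization

Adam (β = 0.9/0.999, lr 1e-3, batch 128) implemented in numpy, with a
plateau scheduler halving the learning rate after 10 epochs without
validation improvement. Validation is an 85–15 cell split; validation
forward passes are deterministic (z = μ). One global seed drives the split,
initialization (He-style), batch shuffling, and ε draws, so two runs with the
same seed and thread count produce byte-identical outputs. The log-variance
head is clamped to ±15 for numerical safety; non-finite losses raise with
the epoch index rather than silently diverging.

### Inference

`transform` / `infer_activities` run eval-mode (z = μ, no sampling) and blend
the clipped ULM estimate with the decoder head at the model's final α. This
makes the untrained α = 0 model exactly the ReLU-clipped ULM scorer — a
useful sanity anchor tested against an independent least-squares oracle.

### Per-cluster fine-tuning

Each cluster (≥ 20 cells; smaller clusters are skipped with a warning) gets a
copy of the global parameters, trained further on its own cells with α held
at α_max, the mask held at its terminal (≈ 4.5e-5) value, and γ held at
γ_max, so adaptation is purely data-driven. Defaults are 400 fine-tuning
epochs at half the global learning rate: with mini-batch Adam and a few
hundred cells per cluster, an epoch is only a couple of optimizer steps, and
substantially smaller budgets leave the per-cluster networks still at the
global compromise rather than specialized to cluster-specific regulation;
this budget reliably flips per-cluster weight matrices toward their own
cluster's ground truth in the rewired-simulation benchmark while remaining a
few seconds of compute. Both knobs are configurable.

## Input filtering

`filter_and_align` retains genes expressed (value > 0, which is correct for
both counts and log-normalized data) in ≥ 10 cells and covered by ≥ 1 prior
TF; cells expressing ≥ 3 retained genes; and TFs with ≥ 10 retained targets.
Passes run genes → cells → genes re-checked once against the retained cells
→ TFs; a single re-check avoids an unbounded fixed-point loop and leaves the
operation idempotent on realistic inputs. Duplicate prior edges collapse by
sign majority with ties resolving to +1. Gene matching is exact and
case-sensitive (an `uppercase` fold is available for human symbols).
Standard upstream preprocessing (QC, HVG selection, normalization) is left
to the caller; `log1p_cpm` is provided as a convenience.

## Synthetic data

The generator emulates the controlled regime the model assumes: a signed
truth GRN (15 targets per TF, log-normal magnitudes, 30% repressive edges by
default), Gamma-distributed activities (shape 4) with mean 5 where a TF is
"on" in the cell's cluster and 0.5 elsewhere, expression
`activities · W_truth + N(0, 0.5)` clipped at zero, optional Bernoulli
dropout, and an exported prior whose edges can be partially replaced by
false edges (`prior_corruption`). The first `n_clusters` TFs are
deterministically exclusive markers of one cluster each, guaranteeing
cluster-specific regulators for differential and marker tests. Per-cluster
truth variants rewire a configurable fraction of each TF's edges.
Noise and dropout derive from fixed substreams of the seed, so
`simulate_knockdown` (scaling one TF's truth activity, default to 10%)
regenerates expression with identical noise — isolating the knockdown's
causal effect.

What the simulator does *not* model: count noise (no negative-binomial
sampling; a flagged extension), library-size variation, batch effects,
doublets, or TF–TF cooperativity. Passing recovery tests therefore
demonstrates that the inference machinery works when the generative
assumptions hold, not that the model is robust to every artefact of real
scRNA-seq data.

## Evaluation procedures

- Clustering: Leiden (RB-configuration, seeded, 2 iterations) on a k = 15
  Euclidean kNN graph of the activity matrix, swept over resolutions
  0.2–3.0; each cluster receives its modal true label (ties lexicographic)
  before ARI / NMI / macro-F1. The additional "AUC" column is a macro
  one-vs-rest AUC over assigned-label indicators — a coarse, label-level
  construction reported for completeness and excluded from any strong claim.
- Dropout robustness: entries zeroed independently with probability p
  (seeded), then the clustering pipeline re-run on re-inferred activities.
- GRN recovery: AUROC and average-precision AUPRC of |W| against the binary
  truth, restricted to the TF *and* gene identifier intersection (gene-only
  intersection leaves scores undefined when TF sets differ); midrank tie
  handling. Verified against an exhaustive threshold-enumeration oracle.
- Stratified sketching: Leiden pseudo-clusters on a PCA embedding, then a
  seeded uniform within-cluster split across subsets (round-robin over a
  shuffled order), giving per-cluster subset sizes within ±1 — the
  proportional-representation guarantee. `_within_cluster_order` is the hook
  for plugging a geometric-sketching backend.
- Knockdown scoring: `log2((mean_kd + ε)/(mean_ctrl + ε))` with ε = 1e-9
  (activities can be exactly 0 under ReLU) and a two-sided Wilcoxon rank-sum
  test; Benjamini–Hochberg across TFs where several are screened.
- Differential TF activity: one-vs-rest Wilcoxon rank-sum per (TF, group),
  BH across TFs within each group, retention at adjusted P < 0.05, ranking
  by LFC descending. LFCs are computed on raw (not min-max scaled)
  activities, keeping them invariant to the per-TF scaling choice.
- GRN similarity across cell types: per-TF min-max scaling of absolute
  weights, flattening, pairwise Pearson, average-linkage clustering on
  1 − r (the linkage choice is a default; the similarity matrix is exposed
  for any other linkage).

## Problem sizes

Defaults were chosen so every benchmark is a desk-scale experiment: 600
cells × 200 genes × 15 TFs for the standard simulation, 1000 × 400 × 25 with
30% prior corruption for edge-recovery, 150 global training epochs at most.
These sizes exercise every code path while keeping the full test suite and
the acceptance script in the tens of seconds on a single CPU.

## Known limitations

- Gaussian reconstruction restricts input to (approximately) continuous
  log-scale data; raw counts should be transformed first.
- TF activities are identified only up to the information in the prior:
  a TF silent in a cluster has unidentifiable targets there, and its
  fine-tuned row remains near the global solution.
- The ULM estimate treats genes as independent observations within a cell;
  correlated regulons inflate each other's scores.
- The clustering "AUC" construction is a placeholder, as noted above.
- Determinism guarantees are per-machine/per-thread-count (BLAS reduction
  order); cross-platform bit-equality is not promised.
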