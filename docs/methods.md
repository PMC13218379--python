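# Methods

## The problem

Drug-synergy panels report a scalar interaction score (Loewe, HSA,
Bliss, ZIP or S-score) for a drug pair tested on a cell line.  Models
that regress these scores on cell-line omics profiles face a
confounding problem: thousands of genes co-vary with the handful that
actually mediate the combined drug response, so a flexible model can
fit spurious gene-synergy correlations that do not transfer.  The
package implements a causal-adjustment module that splits the gene
panel, per cell line, into a *causal* channel trained against the
observed score and a *trivial* channel trained against an all-zero
null-information target, with the intent that genes whose information
genuinely drives synergy accumulate in the causal channel.

## Model

For a cell-line profile `C ∈ R^{F×N}` (F omic layers, N genes):

1. **Gene attention.** A parameter-shared fully connected map turns
   each gene's F-vector into a feature `g_i`; a two-channel projection
   plus a per-gene learnable logit bias gives logits `z_i ∈ R²`, and a
   softmax over the two channels yields `(α_c_i, α_t_i)` with
   `α_c_i + α_t_i = 1`.  The stacked channels are the complementary
   soft masks `M_c` and `M_t = 1 − M_c`.
2. **Disentangled profiles.** `G_c = C ⊙ M_c`, `G_t = C ⊙ M_t`
   (Hadamard product broadcast over omic layers), so `G_c + G_t = C`.
3. **Drug encoders (shared across branches).**  Sequence pathway:
   SMILES tokens are embedded, combined additively with a unit-row-norm
   sinusoidal positional encoding, and layer-normalized per position,
   `D = LN(T ⊕ P)`.  Graph pathway: RDKit atom/bond graphs through one
   4-head graph-attention layer cascaded into graph convolutions with
   symmetric-normalized adjacency, mean-pooled.  Pooled drug vectors
   pass through a small shared-space projection MLP.
4. **Fusion and heads (duplicated per branch, disjoint parameters).**
   The `mlp` and `graph` backbones encode the masked profile with a
   dense layer and concatenate `G_i ‖ D_A ‖ D_B` into an MLP ending in
   Tanh.  The `xattn` backbone treats genes as tokens, runs one
   cross-attention exchange (cell over drugs, each drug over the cell,
   then drug-drug in both directions with shared parameters, each with
   residual + layer norm) and applies the same pooled head.
5. **Dual loss.** `L = MSE(Y_c, y) + MSE(Y_t, 0)` on standardized
   labels.  Reported predictions come from the causal branch only and
   are mapped back to the original score scale.

### Why the per-gene logit bias

With a purely parameter-shared attention map and a single omic layer,
a gene's attention score is a fixed scalar function of its expression
value, so its panel-mean causal score is a functional of its value
distribution alone: two genes with the same marginal distribution can
never rank differently, and causal-gene recovery is impossible by
construction.  The per-gene two-channel bias (zero-initialized) is the
minimal addition that lets a gene acquire a panel-wide causal
propensity while the shared map still modulates the score per cell
line; attribution stays traceable to individual genes.

### What makes the masks informative

The dual loss alone does not force mask specialization: a dense cell
encoder can rescale any gene, so the causal fit is nearly invariant to
per-gene mask values, and the trivial branch's null target is
satisfiable regardless of its input (at long horizons its
variance-minimizing gradient in fact pushes *all* mask entries toward
the causal channel — a degenerate optimum).  Three ingredients break
the invariance and make the attention informative; all act on training
dynamics or parametrization, and the mask mechanism itself remains the
plain soft complementary pair:

* **Weight-normalized cell encoders.**  In the causal and trivial
  branches the encoder's per-gene fan-out vectors are rescaled to unit
  norm in the forward pass, so per-gene input scale is carried
  exclusively by the mask — attention cannot be compensated away by
  the encoder.  (The single-branch baseline keeps an unconstrained
  dense encoder, its natural form.)
* **Weight decay** (decoupled, default 1e-3) keeps memorization-driven
  encoder weight in check during the main fit.
* **Bilevel mask refinement.**  After the main fit, every parameter
  except the per-gene logit biases is frozen and the causal-branch MSE
  is minimized with full-batch gradients on the *validation* split
  (the trivial term is omitted there: against a frozen net it
  contributes only a uniform push on every gene).  Held-out data is
  what distinguishes causal from trivial genes — attention that only
  serves training-set memorization does not transfer.  Because the N
  biases can overfit the refinement split, refinement is bagged:
  several replicates start from uniform masks (`bias = 0`, keeping
  softmax gradients alive) and fit random halves of the split, and the
  resulting biases are averaged.  A brief re-fit of the full network
  under the refined masks, followed by a second refinement pass,
  re-anchors the net on retained genes (defaults: 300 full-batch steps
  per replicate, 4 replicates, 2 cycles, 10 re-fit epochs, refinement
  lr 1e-2 with decay 0.1 on the biases).

At the package's desk-scale study conditions this pipeline yields a
clearly asymmetric ablation (zeroing causal-ranked genes hurts far
more than trivial-ranked genes, every replicate) and causal/decoy/noise
mean scores ordered as expected, but the per-gene ranking remains
noisy; see Known limitations.

## Synthetic study conditions

The generator plants a known causal structure so recovery is scorable:
gene values `x_{c,g} ~ N(μ_g, σ_g²)` with `μ_g ~ N(0,1)`,
`σ_g ~ U(0.5, 1.5)`; each causal gene is paired with a decoy whose
z-scores correlate with it at `confound_rho`; extra omic layers are
noisy copies of layer 1 (correlation 0.7).  Drugs carry latent vectors
`u ~ N(0, I_8)` and distinct small valid SMILES; labels are
`y = (u_A·u_B) · Σ_g w_g x̄_{c,g} + ε`, `w_g ~ ±U(0.5, 1.5)`,
`ε ~ N(0, noise_sd²)`, standardized to zero mean and unit variance.
The default conditions are n_cells=60, n_genes=300, k_causal=15,
n_drugs=30, n_examples=6000, noise_sd=0.3, confound_rho=0.6.

The generator emulates the *structure* of a synergy panel (a planted
sparse causal gene set, confounded decoys, symmetric pair
interactions), not its biology: real synergy labels are not linear in
expression, real drug effects are not captured by an 8-dimensional
latent dot product, and real omics layers are not noisy copies of one
another.  Passing the recovery tests therefore shows the machinery can
separate planted causal structure from confounded and irrelevant
variation at this scale — not that it recovers biological drivers on
real panels.

## Training defaults and rationale

Adam, lr 3e-3 halved on validation plateau, up to 250 epochs with
early stopping (patience 40), batch 128, SiLU hidden activations,
head hidden sizes (128, 64), d_model 64, d_g 32, weight decay 1e-3,
plus the mask-refinement schedule above.  The label surface is a
three-way product
(drug-pair latent × cell signal), which a concatenation MLP learns
slowly; the higher initial learning rate, SiLU (whose even-order term
helps product structure), the shared-space drug projection, and the
plateau schedule were chosen to reach a stable fit within a desk-scale
CPU budget.  Training runs in float32; reference computations and
gradient checks run in float64 (the engine preserves whichever dtype
it is given).

## Evaluation suite

* Regression metrics (MAE, RMSE, R², PCC) with explicit degeneracy
  flags instead of silent NaNs.
* Ablation: genes ranked by run-mean attention per branch (ties by
  gene index), top-k columns zeroed at inference, metrics recomputed;
  k defaults to 10% of the panel.
* Few-shot: training fractions {0.3, 0.5, 0.7} on a fixed test split;
  exact least-squares slope of metric vs fraction.
* Causal-score statistics: per-gene pooled mean/sd over (cell, run)
  via Welford's streaming update; exported as a volcano-style table
  and a ranked two-column gene list consumable by enrichment tools.
* Mean within-class distance: mean Euclidean distance of each
  embedding to its class centroid, averaged over points (the
  formulation is fixed here; only direction-of-change claims should be
  read across formulations).
* Integrated Gradients on the causal-branch output with respect to the
  raw profile (mask included in the attribution path), midpoint-rule
  Riemann sum: exact for quadratic models, completeness gap
  O(1/steps²) otherwise.  Baseline defaults to the zero profile.

## Numerical choices and degenerate inputs

Labels are standardized because the head ends in Tanh while synergy
scores are unbounded; the inverse transform is applied at prediction
time, and the null-information target 0 is then the label mean.
Standardized Gaussian labels exceed the Tanh range for ~32% of
examples; correlation-based metrics are unaffected, absolute errors
saturate mildly.  Softmax is computed with max-shift stabilization;
attention masking uses additive −1e30.  Zero-variance targets flag R²
and PCC as undefined rather than returning NaN.  Empty gene panels,
empty training splits, k > N ablations, and non-finite losses raise
typed errors.

## Known limitations

* The disentanglement pressure is dynamic, not structural: masks carry
  causal ranking because of the decay/lr mechanism described above,
  and the separation margin shrinks if training stops very early.
* The trivial branch's null objective admits the degenerate global
  mask optimum discussed above; the per-gene biases make the ranking
  robust to it, but absolute score levels are not calibrated across
  runs (only within-run rankings are used).
* Pair-swap symmetry of predictions is encouraged by the symmetric
  generator but not enforced by the architecture; it is monitored, not
  asserted.
* The autodiff engine is single-threaded CPU numpy; it is adequate for
  the desk-scale panels here and validated by finite differences, but
  it is not a general deep-learning runtime.
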