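# cads — causal disentanglement for drug-synergy regression

`cads` separates *causal* from *trivial* genes while learning to
predict drug-combination synergy scores from cell-line omics profiles
and drug structures.  It is aimed at computational pharmacologists who
want synergy regressors whose gene usage is inspectable: which genes
does the model causally rely on, and does performance actually depend
on them?

## The model

For a cell-line profile `C ∈ R^{F×N}` the package learns complementary
soft masks over genes.  Per gene `i`, two-channel attention gives
weights `(α_c_i, α_t_i)` with `α_c_i + α_t_i = 1`; the masks
`M_c = [α_c_i]`, `M_t = 1_N − M_c` split the profile into

    G_c = C ⊙ M_c        G_t = C ⊙ M_t        (G_c + G_t = C)

Two structurally identical encoder branches with disjoint parameters
consume the two halves together with shared drug representations
(SMILES token sequences with unit-norm positional encodings, or RDKit
molecular graphs through GAT/GCN layers; fused by concatenation + MLP
or by cross-attention exchanges, ending in a Tanh head).  The branches
are trained jointly with

    L = MSE(Y_c, y) + MSE(Y_t, 0)

so the causal branch regresses the observed synergy score while the
trivial branch is pulled toward an uninformative constant.  `α_c_i` is
gene `i`'s *causal score*; after a bilevel mask-refinement pass on
held-out data its panel-mean ranks genes by transferable, non-spurious
relevance.  Predictions always come from the causal branch.

Because real synergy panels never disclose which genes are causal, the
package ships a synthetic-data generator with planted ground truth
(causal genes, confounded decoy genes, symmetric drug-pair latents) on
which recovery, ablation asymmetry and few-shot robustness are
measurable.  See `docs/methods.md` for the generative model, training
mechanics and their rationale.

## Worked example

```sh
cads simulate --n-cells 20 --n-genes 60 --k-causal 6 --n-drugs 10 \
              --n-examples 800 --seed 7 --out data/
cads train --data data/ --epochs 40 --seed 7 --out run/
cads ablate --run run/ --branch causal --k 6
```

The ablation command prints (values from this exact invocation,
abbreviated to three decimals):

```json
{
 "branch": "causal",
 "k_masked": 6,
 "before": {"MAE": 0.385, "RMSE": 0.697, "R2": 0.626, "PCC": 0.871, "n": 120, "split": "test"},
 "after":  {"MAE": 0.447, "RMSE": 0.722, "R2": 0.599, "PCC": 0.826, "n": 120, "split": "test"},
 "loss": {"MAE": 0.063, "RMSE": 0.025, "R2": 0.027, "PCC": 0.044}
}
```

Reading it: on the held-out split the trained model reaches Pearson
r = 0.871 (standardized scores).  Zero-masking the six genes the model
ranks most causal costs 0.025 RMSE and 0.044 PCC; repeating with
`--branch trivial` costs essentially nothing (ΔRMSE ≈ 2e-7) — the
model's predictions genuinely depend on its causal-ranked genes and
not on its trivial-ranked ones.

The same workflow runs from Python (`cads.synthdata.simulate`,
`cads.train`, `cads.evalsuite.ablate_top_genes`), which is what the
test suite and acceptance script do.

## Layout

| module | contents |
|---|---|
| `cads.synthdata` | planted-truth synergy dataset generator |
| `cads.drug_encoder` | SMILES tokenizer, positional encoding, sequence & graph encoders |
| `cads.causal_mask` | gene attention, complementary masks, masked profiles |
| `cads.fusion` | cross-/self-attention, drug-cell exchanges, prediction heads |
| `cads.cads_model` | dual-branch assembly, dual loss, training & prediction |
| `cads.evalsuite` | metrics, ablation, few-shot, causal-score stats, Integrated Gradients |
| `cads.io_cli` | readers/writers, run artifacts, `cads` command line |
| `cads._tensor` | numpy reverse-mode autodiff engine |
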