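"""Dual-branch causal-disentanglement model for synergy regression.

The encoder is split into two structurally identical branches with
disjoint parameters: the *causal* branch consumes the causally masked
cell profile ``Gc`` and is trained against the observed synergy score,
while the *trivial* branch consumes the complementary profile ``Gt``
and is trained against an all-zero "null information" label.  The two
mean-squared errors are simply summed:

    L = MSE(Yc, y) + MSE(Yt, 0)

Both branches share the drug encoders and the single mask encoder, so
gradients from both objectives shape the per-gene attention that
produces the masks: genes that help the causal fit are pulled into the
causal channel, and the trivial branch is pushed toward predicting a
constant regardless of its input.  The reported prediction always comes
from the causal branch; the trivial branch is a regularizing head.

Three backbones are supported: ``mlp`` (sequence-encoded drugs,
concatenation + MLP fusion), ``graph`` (GAT/GCN-encoded drugs,
concatenation + MLP fusion) and ``xattn`` (sequence-encoded drugs with
self-attention, cross-attention drug-cell fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._tensor import (MLP, Adam, Linear, Module, Tensor, concatenate,
                      layer_norm, softmax)
from .causal_mask import MaskEncoder
from .drug_encoder import (GraphEncoder, SequenceEncoder, build_graph,
                           build_vocab, tokenize_smiles)
from .fusion import ExchangeBlock, MultiHeadAttention, PredictionHead, pool
from .synthdata import Standardization

__all__ = [
    "TrainConfig",
    "DualPrediction",
    "LossReport",
    "DualBranchModel",
    "TrainedModel",
    "forward",
    "loss",
    "train",
    "predict",
]

BACKBONES = ("mlp", "graph", "xattn")


@dataclass
class TrainConfig:
    backbone: str = "mlp"
    d_model: int = 64
    d_g: int = 32
    n_heads: int = 4
    hidden: tuple[int, ...] = (128, 64)
    max_len: int = 128
    lr: float = 3e-3
    epochs: int = 250
    batch_size: int = 128
    patience: int = 40
    val_frac: float = 0.15
    test_frac: float = 0.15
    split_mode: str = "example"        # "example" | "leave_cell_out"
    use_cads: bool = True              # False = single-branch baseline, no masks
    activation: str = "silu"           # hidden activation of the MLP head
    weight_decay: float = 1e-3
    lr_decay: float = 0.5              # multiply lr by this on val plateau
    mask_lr_mult: float = 1.0          # lr multiplier for per-gene mask biases
    mask_update: str = "step"          # "epoch": biases step on epoch-mean grad
    mask_finetune_epochs: int = 300    # full-batch bias-only refinement steps
    mask_refine_lr: float = 1e-2       # refinement-phase Adam learning rate
    mask_refine_wd: float = 0.1        # weight decay on biases during refinement
    mask_refine_split: str = "val"     # "val" examples or held-out "cells"
    mask_refine_cycles: int = 2        # alternations of refine / re-fit
    mask_refine_reps: int = 4          # bagged refinements on val subsamples
    refit_epochs: int = 10             # re-fit epochs between refinements
    l1_cell: float = 0.0               # L1 on cell-encoder weights (per branch)
    dtype: str = "float32"             # training precision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        for name in ("d_model", "d_g", "n_heads", "lr", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.hidden = tuple(self.hidden)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d


@dataclass
class DualPrediction:
    Yc: np.ndarray
    Yt: np.ndarray
    y_hat: np.ndarray          # de-standardized causal-branch prediction
    Yc_t: Tensor | None = None  # graph-connected tensors kept for training
    Yt_t: Tensor | None = None


@dataclass
class LossReport:
    L: float
    L_causal: float
    L_trivial: float

    def __post_init__(self) -> None:
        if abs(self.L - (self.L_causal + self.L_trivial)) > 1e-7:
            raise ValueError("total loss must equal the sum of its branch terms")


class _Branch(Module):
    """One cell-conditioned pathway (cell encoder + fusion + head).

    ``Fc`` and ``Ft`` are two instances of this class with independent
    parameters and identical architecture.
    """

    def __init__(self, backbone: str, n_omics: int, n_genes: int,
                 d_model: int, n_heads: int, hidden: tuple[int, ...],
                 rng: np.random.Generator, activation: str = "relu",
                 normalize_cell: bool = True):
        self.backbone = backbone
        self.normalize_cell = normalize_cell
        if backbone in ("mlp", "graph"):
            self.cell_enc = Linear(n_omics * n_genes, d_model, rng)
        else:
            self.gene_proj = Linear(n_omics, d_model, rng)
            self.exchange = ExchangeBlock(d_model, n_heads, rng)
        self.head = PredictionHead(d_model, d_model, hidden, rng,
                                   activation=activation)

    # vectorized cell representation for the concat+MLP backbones
    def cell_vectors(self, G_flat: Tensor) -> Tensor:
        W = self.cell_enc.W
        if self.normalize_cell:
            # unit-norm fan-out per gene: per-gene scale is carried
            # exclusively by the soft mask, so attention cannot be
            # compensated away by the encoder
            W = W * ((W * W).sum(axis=1, keepdims=True) + 1e-8) ** -0.5
        return (G_flat @ W + self.cell_enc.b).tanh()


class DualBranchModel(Module):
    """Shared drug encoders + mask encoder, duplicated branch encoders."""

    def __init__(self, config: TrainConfig, n_omics: int, gene_ids: list[str],
                 drugs, score_sd: Standardization | None = None):
        self.config = config
        self.gene_ids = list(gene_ids)
        self.n_genes = len(gene_ids)
        self.n_omics = n_omics
        root = np.random.SeedSequence(config.seed)
        r_mask, r_drug, r_fc, r_ft, r_misc = (np.random.default_rng(s)
                                              for s in root.spawn(5))
        self.mask_encoder = MaskEncoder(n_omics, d_g=config.d_g, rng=r_mask,
                                        n_genes=self.n_genes)
        self.drug_ids = [d.drug_id for d in drugs]
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self.smiles = {d.drug_id: d.smiles for d in drugs}
        if config.backbone == "graph":
            self.graph_encoder = GraphEncoder(d_hidden=config.d_model,
                                              d_out=config.d_model,
                                              n_heads=config.n_heads, rng=r_drug)
            self._graphs = [build_graph(d.smiles) for d in drugs]
        else:
            self.vocab = build_vocab([d.smiles for d in drugs])
            self.seq_encoder = SequenceEncoder(self.vocab, config.d_model,
                                               max_len=config.max_len, rng=r_drug)
            self._seqs = [tokenize_smiles(d.smiles, self.vocab, config.max_len)
                          for d in drugs]
            # common token length for vectorized embedding
            self._L = max(s.length for s in self._seqs)
            self._tok = np.stack([s.tokens[:self._L] for s in self._seqs])
            self._tokmask = np.stack([s.pad_mask[:self._L] for s in self._seqs])
            if config.backbone == "xattn":
                self.drug_msa = MultiHeadAttention(config.d_model,
                                                   config.n_heads, r_drug)
        # shared-space projection of drug representations (row-wise MLP)
        self.drug_proj = MLP(config.d_model, [2 * config.d_model],
                             config.d_model, r_misc,
                             activation=config.activation)
        self.Fc = _Branch(config.backbone, n_omics, self.n_genes,
                          config.d_model, config.n_heads, config.hidden, r_fc,
                          activation=config.activation,
                          normalize_cell=config.use_cads)
        self.Ft = _Branch(config.backbone, n_omics, self.n_genes,
                          config.d_model, config.n_heads, config.hidden, r_ft,
                          activation=config.activation,
                          normalize_cell=config.use_cads)
        self._np_dtype = np.float32 if config.dtype == "float32" else np.float64
        self.astype(self._np_dtype)
        if config.backbone != "graph":
            self.seq_encoder.pos.P = self.seq_encoder.pos.P.astype(self._np_dtype)

    # -- shared sub-computations ---------------------------------------------
    def masks_for_cells(self, C_all: np.ndarray | Tensor) -> tuple[Tensor, Tensor]:
        """Vectorized two-channel gene attention for a (U, F, N) stack.

        Returns (alpha_c, alpha_t), each (U, N)."""
        C_all = C_all if isinstance(C_all, Tensor) else Tensor(C_all)
        U, F, N = C_all.shape
        cols = C_all.transpose(0, 2, 1).reshape(U * N, F)
        feats = self.mask_encoder.fc(cols).tanh()
        logits = self.mask_encoder.W(feats).reshape(U, N, 2)
        if self.mask_encoder.gene_bias is not None:
            logits = logits + self.mask_encoder.gene_bias.reshape(1, N, 2)
        alpha = softmax(logits, axis=-1)
        return (alpha[:, :, 0], alpha[:, :, 1])

    def drug_matrix(self) -> tuple[Tensor, np.ndarray]:
        """All drugs' pooled embeddings, (n_drugs, d_model)."""
        cfg = self.config
        if cfg.backbone == "graph":
            rows = [pool(self.graph_encoder(g).Dk).reshape(1, -1)
                    for g in self._graphs]
            return self.drug_proj(concatenate(rows, axis=0)), None
        emb = self.seq_encoder.embedding[self._tok]          # (n_drugs, L, d)
        x = emb + Tensor(self.seq_encoder.pos.P[: self._L][None, :, :])
        x = layer_norm(x)                                    # per position
        if cfg.backbone == "xattn":
            rows = []
            for i in range(len(self.drug_ids)):
                xi = x[i]
                mask_i = self._tokmask[i]
                att = self.drug_msa.attend(xi, xi, kv_mask=mask_i)
                rows.append(pool(layer_norm(xi + att), mask_i).reshape(1, -1))
            return self.drug_proj(concatenate(rows, axis=0)), None
        w = (self._tokmask / self._tokmask.sum(axis=1, keepdims=True)).astype(
            self._np_dtype)
        pooled = (x * Tensor(w[:, :, None])).sum(axis=1)
        return self.drug_proj(pooled), None

    def drug_tokens(self, idx: int) -> tuple[Tensor, np.ndarray]:
        """Per-token drug representation for the cross-attention pathway."""
        seq = self._seqs[idx]
        emb = self.seq_encoder.embedding[seq.tokens[: seq.length]]
        x = layer_norm(emb + Tensor(self.seq_encoder.pos.P[: seq.length]))
        att = self.drug_msa.attend(x, x)
        return self.drug_proj(layer_norm(x + att)), np.ones(seq.length, dtype=bool)

    # -- forward --------------------------------------------------------------
    def forward_batch(self, C_all: np.ndarray, cell_of: np.ndarray,
                      a_of: np.ndarray, b_of: np.ndarray) -> tuple[Tensor, Tensor]:
        """Batched forward; returns (Yc, Yt) tensors of shape (B,).

        ``C_all`` stacks the unique cell profiles referenced by
        ``cell_of``; ``a_of``/``b_of`` index into the model's drug list.
        """
        cfg = self.config
        if not isinstance(C_all, Tensor):
            C_all = Tensor(np.asarray(C_all, dtype=self._np_dtype))
        C_t = C_all
        U, F, N = C_t.shape
        if cfg.use_cads:
            alpha_c, alpha_t = self.masks_for_cells(C_t)
            Gc = C_t * alpha_c.reshape(U, 1, N)
            Gt = C_t * alpha_t.reshape(U, 1, N)
        else:
            # single-branch baseline: the encoder consumes the raw profile
            Gc, Gt = C_t, None
        if cfg.backbone in ("mlp", "graph"):
            drugs, _ = self.drug_matrix()
            cell_c = self.Fc.cell_vectors(Gc.reshape(U, F * N))
            zc = concatenate([cell_c[cell_of], drugs[a_of], drugs[b_of]], axis=1)
            Yc = self.Fc.head(zc).reshape(-1)
            if not cfg.use_cads:
                return Yc, Tensor(np.zeros(len(cell_of)))
            cell_t = self.Ft.cell_vectors(Gt.reshape(U, F * N))
            zt = concatenate([cell_t[cell_of], drugs[a_of], drugs[b_of]], axis=1)
            Yt = self.Ft.head(zt).reshape(-1)
            return Yc, Yt
        # cross-attention pathway: per-example fusion
        drug_cache = {int(i): self.drug_tokens(int(i))
                      for i in np.unique(np.concatenate([a_of, b_of]))}
        branches = [(self.Fc, Gc)]
        if cfg.use_cads:
            branches.append((self.Ft, Gt))
        outs_c, outs_t = [], []
        for u, a, b in zip(cell_of, a_of, b_of):
            DA, _ = drug_cache[int(a)]
            DB, _ = drug_cache[int(b)]
            for branch, G in branches:
                tokens = branch.gene_proj(G[int(u)].T)       # (N, d_model)
                state = branch.exchange(tokens, DA, DB)
                z = concatenate([pool(state.Gi_prime), pool(state.DA),
                                 pool(state.DB)], axis=0).reshape(1, -1)
                out = branch.head(z).reshape(-1)
                (outs_c if branch is self.Fc else outs_t).append(out)
        Yc = concatenate(outs_c, axis=0)
        Yt = concatenate(outs_t, axis=0) if outs_t else Tensor(np.zeros(len(cell_of)))
        return Yc, Yt


@dataclass
class TrainedModel:
    model: DualBranchModel
    config: TrainConfig
    standardization: Standardization
    history: list[dict] = field(default_factory=list)
    split: dict | None = None           # index arrays: train/val/test
    cell_index: dict | None = None


# --------------------------------------------------------------------------
# functional API
# --------------------------------------------------------------------------

def _index_batch(dataset, examples):
    cell_ids = {p.cell_id: i for i, p in enumerate(dataset.profiles)}
    didx = {d.drug_id: i for i, d in enumerate(dataset.drugs)}
    try:
        cells = np.array([cell_ids[e.cell_id] for e in examples])
        a = np.array([didx[e.drug_a_id] for e in examples])
        b = np.array([didx[e.drug_b_id] for e in examples])
    except KeyError as err:
        raise KeyError(f"example references unknown entity {err}") from err
    y = np.array([e.y for e in examples])
    return cells, a, b, y


def forward(model: DualBranchModel, dataset, examples,
            std: Standardization | None = None) -> DualPrediction:
    """Run the dual-branch model on a list of examples."""
    cells, a, b, _ = _index_batch(dataset, examples)
    C_all = np.stack([p.C for p in dataset.profiles])
    Yc, Yt = model.forward_batch(C_all, cells, a, b)
    std = std or getattr(dataset, "standardization", None)
    y_hat = std.invert(Yc.data) if std is not None else Yc.data.copy()
    return DualPrediction(Yc=Yc.data.copy(), Yt=Yt.data.copy(), y_hat=y_hat,
                          Yc_t=Yc, Yt_t=Yt)


def loss(pred: DualPrediction, y: np.ndarray) -> tuple[Tensor, LossReport]:
    """Summed dual objective: causal MSE against y, trivial MSE against 0."""
    y = np.asarray(y, dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("labels must be finite")
    Yc = pred.Yc_t if pred.Yc_t is not None else Tensor(pred.Yc)
    Yt = pred.Yt_t if pred.Yt_t is not None else Tensor(pred.Yt)
    ec = Yc - Tensor(y)
    Lc = (ec * ec).mean()
    Lt = (Yt * Yt).mean()
    total = Lc + Lt
    return total, LossReport(L=float(total.data), L_causal=float(Lc.data),
                             L_trivial=float(Lt.data))


def split_dataset(dataset, config: TrainConfig, rng: np.random.Generator):
    n = len(dataset.examples)
    if config.split_mode == "leave_cell_out":
        cells = sorted({e.cell_id for e in dataset.examples})
        cells = list(rng.permutation(cells))
        n_test = max(1, int(round(config.test_frac * len(cells))))
        n_val = max(1, int(round(config.val_frac * len(cells))))
        test_c, val_c = set(cells[:n_test]), set(cells[n_test:n_test + n_val])
        idx = np.arange(n)
        cid = np.array([e.cell_id for e in dataset.examples])
        test = idx[np.isin(cid, list(test_c))]
        val = idx[np.isin(cid, list(val_c))]
        tr = idx[~np.isin(cid, list(test_c | val_c))]
        return tr, val, test
    perm = rng.permutation(n)
    n_test = int(round(config.test_frac * n))
    n_val = int(round(config.val_frac * n))
    return perm[n_test + n_val:], perm[n_test:n_test + n_val], perm[:n_test]


def train(dataset, config: TrainConfig | None = None,
          train_idx: np.ndarray | None = None,
          verbose: bool = False) -> TrainedModel:
    """Minibatch Adam on the summed dual loss with early stopping.

    The best checkpoint by validation RMSE of the causal branch is
    restored before returning.  ``train_idx`` optionally overrides the
    training subset (used by the few-shot protocol); validation and
    test splits are always drawn from the full example list first.
    """
    config = config or TrainConfig()
    root = np.random.SeedSequence(config.seed)
    r_split, r_shuffle = (np.random.default_rng(s) for s in root.spawn(2))
    model = DualBranchModel(config, dataset.profiles[0].C.shape[0],
                            dataset.gene_ids, dataset.drugs)
    refine = np.array([], dtype=int)
    use_refine_cells = (config.use_cads and config.mask_finetune_epochs > 0
                        and config.mask_refine_split == "cells"
                        and config.split_mode == "example"
                        and len(dataset.profiles) >= 8)
    if use_refine_cells:
        # Reserve a cell-line hold-out for mask refinement: those cells'
        # examples never enter the fit, so per-cell memorization carries
        # no signal there and only panel-transferable gene relevance
        # survives.  Evaluation splits are drawn from the remaining
        # cells' examples as usual.
        all_cells = np.array(sorted({p.cell_id for p in dataset.profiles}))
        r_cells = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3]).generate_state(1)[0])
        n_hold = max(2, int(round(0.25 * len(all_cells))))
        held = set(r_cells.choice(all_cells, size=n_hold, replace=False))
        cid = np.array([e.cell_id for e in dataset.examples])
        refine = np.flatnonzero(np.isin(cid, list(held)))
        keep = np.flatnonzero(~np.isin(cid, list(held)))
        perm = r_split.permutation(keep)
        n_test = int(round(config.test_frac * len(perm)))
        n_val = int(round(config.val_frac * len(perm)))
        test = perm[:n_test]
        val = perm[n_test:n_test + n_val]
        tr = perm[n_test + n_val:]
    else:
        tr, val, test = split_dataset(dataset, config, r_split)
    if train_idx is not None:
        tr = np.asarray(train_idx)
    if len(tr) < 1:
        raise ValueError("training split is empty")
    examples = dataset.examples
    cells, a, b, y = _index_batch(dataset, examples)
    C_all = np.stack([p.C for p in dataset.profiles])
    params = model.parameters()
    gene_bias = (model.mask_encoder.gene_bias if config.use_cads
                 and model.mask_encoder.gene_bias is not None else None)
    epoch_bias = gene_bias is not None and config.mask_update == "epoch"
    scales = [1.0] * len(params)
    if gene_bias is not None:
        idx = [i for i, p in enumerate(params) if p is gene_bias][0]
        scales[idx] = 0.0 if epoch_bias else config.mask_lr_mult
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay,
               lr_scale=scales)
    bias_opt = (Adam([gene_bias], lr=config.lr * config.mask_lr_mult,
                     weight_decay=config.weight_decay) if epoch_bias else None)
    best = (np.inf, None, -1)
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = r_shuffle.permutation(tr)
        ep_loss = ep_lc = ep_lt = 0.0
        n_batches = 0
        if bias_opt is not None:
            bias_accum = np.zeros_like(gene_bias.data)
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            Yc, Yt = model.forward_batch(C_all, cells[sel], a[sel], b[sel])
            pred = DualPrediction(Yc=Yc.data, Yt=Yt.data, y_hat=Yc.data,
                                  Yc_t=Yc, Yt_t=Yt)
            total, rep = loss(pred, y[sel])
            if config.l1_cell and config.backbone in ("mlp", "graph"):
                for br in (model.Fc, model.Ft):
                    W = br.cell_enc.W
                    total = total + (W.relu() + (-W).relu()).sum() * config.l1_cell
            if not np.isfinite(rep.L):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={rep.L}")
            opt.zero_grad()
            total.backward()
            if bias_opt is not None and gene_bias.grad is not None:
                bias_accum += gene_bias.grad
            opt.step()
            ep_loss += rep.L
            ep_lc += rep.L_causal
            ep_lt += rep.L_trivial
            n_batches += 1
        if bias_opt is not None and n_batches:
            # per-gene mask biases move once per epoch on the epoch-mean
            # gradient: averaging cuts minibatch noise so the small
            # systematic causal/trivial drift dominates the update
            bias_opt.zero_grad()
            gene_bias.grad = bias_accum / n_batches
            bias_opt.step()
        # validation
        Yc_v, _ = model.forward_batch(C_all, cells[val], a[val], b[val])
        val_rmse = float(np.sqrt(np.mean((Yc_v.data - y[val]) ** 2)))
        history.append({
            "epoch": epoch,
            "train_loss": ep_loss / n_batches,
            "train_loss_causal": ep_lc / n_batches,
            "train_loss_trivial": ep_lt / n_batches,
            "val_rmse": val_rmse,
        })
        if verbose:
            print(f"epoch {epoch:3d}  loss {ep_loss / n_batches:.4f}  "
                  f"val_rmse {val_rmse:.4f}")
        if val_rmse < best[0] - 1e-6:
            best = (val_rmse, model.state_dict(), epoch)
        elif epoch - best[2] >= config.patience:
            break
        elif (config.lr_decay < 1.0 and epoch - best[2] > 0
              and (epoch - best[2]) % max(2, config.patience // 2) == 0):
            opt.lr = max(opt.lr * config.lr_decay, 1e-5)
    if best[1] is not None:
        model.load_state_dict(best[1])
    if gene_bias is not None and config.mask_finetune_epochs > 0:
        # Mask refinement (bilevel, DARTS-style): every parameter except
        # the per-gene biases is frozen and the same dual objective is
        # minimized on the *validation* split with full-batch gradients.
        # Held-out data is what separates causal from trivial genes —
        # memorization-driven attention does not transfer to it — and
        # full batches remove the minibatch noise that otherwise turns
        # the tiny per-gene signal into a random walk.  Refinement
        # alternates with brief re-fits so the network re-anchors on the
        # genes the masks retain, exposing weaker causal genes to the
        # next refinement pass.
        ft = refine if len(refine) else (val if len(val) else tr)
        r_refine = np.random.default_rng(np.random.SeedSequence([config.seed, 5]).generate_state(1)[0])
        for cycle in range(config.mask_refine_cycles):
            # bagged refinement: the per-gene biases have enough capacity
            # to overfit the refinement split, so each replicate starts
            # from uniform masks (main-phase bias values are optimizer
            # dynamics, often saturated) and fits a random half of it;
            # subsample-specific overfit averages out across replicates
            # while transferable gene signal is consistent
            collected = []
            ft_cells = np.unique(cells[ft]) if len(ft) else np.array([])
            for rep_i in range(config.mask_refine_reps):
                gene_bias.data[:] = 0.0
                if (config.mask_refine_reps > 1 and len(ft_cells) >= 4
                        and config.mask_refine_split == "cells"):
                    # bag by cell line: each replicate sees a different
                    # half of the held-out cells, so cell-specific
                    # overfit decorrelates across replicates
                    pick = r_refine.choice(ft_cells, size=len(ft_cells) // 2,
                                           replace=False)
                    sub = ft[np.isin(cells[ft], pick)]
                elif config.mask_refine_reps > 1:
                    sub = r_refine.choice(ft, size=max(1, len(ft) // 2),
                                          replace=False)
                else:
                    sub = np.asarray(ft)
                ft_opt = Adam([gene_bias], lr=config.mask_refine_lr,
                              weight_decay=config.mask_refine_wd)
                for step in range(config.mask_finetune_epochs):
                    # causal term only: the trivial branch's null target
                    # contributes just a uniform push on every gene here
                    Yc, _ = model.forward_batch(C_all, cells[sub], a[sub],
                                                b[sub])
                    ec = Yc - Tensor(y[sub].astype(Yc.data.dtype))
                    Lc = (ec * ec).mean()
                    ft_opt.zero_grad()
                    Lc.backward()
                    ft_opt.step()
                collected.append(gene_bias.data.copy())
                history.append({"epoch": len(history),
                                "train_loss": float(Lc.data),
                                "train_loss_causal": float(Lc.data),
                                "train_loss_trivial": 0.0,
                                "val_rmse": float(np.sqrt(Lc.data)),
                                "phase": f"mask_refine_{cycle}_{rep_i}"})
            gene_bias.data = np.mean(collected, axis=0)
            if cycle == config.mask_refine_cycles - 1:
                break
            for _ in range(config.refit_epochs):
                order = r_shuffle.permutation(tr)
                for start in range(0, len(order), config.batch_size):
                    sel = order[start:start + config.batch_size]
                    Yc, Yt = model.forward_batch(C_all, cells[sel], a[sel],
                                                 b[sel])
                    pred = DualPrediction(Yc=Yc.data, Yt=Yt.data, y_hat=Yc.data,
                                          Yc_t=Yc, Yt_t=Yt)
                    total, _ = loss(pred, y[sel])
                    opt.zero_grad()
                    total.backward()
                    opt.step()
    return TrainedModel(model=model, config=config,
                        standardization=dataset.standardization,
                        history=history,
                        split={"train": tr, "val": val, "test": test,
                               "refine": refine})


def predict(trained: TrainedModel, dataset, examples) -> DualPrediction:
    """De-standardized predictions from the causal branch (trivial branch
    exposed alongside for diagnostics)."""
    model = trained.model
    if [p.cell_id for p in dataset.profiles] and \
            dataset.gene_ids != model.gene_ids:
        raise ValueError("dataset gene panel does not match the trained model")
    return forward(model, dataset, examples, std=trained.standardization)
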