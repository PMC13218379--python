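"""Drug-cell fusion: cross-attention / self-attention exchanges and heads.

The attention-based pathway runs, per branch ``i`` (causal or trivial):

1. drug-cell exchange — the masked cell representation attends over the
   two drugs' tokens and each drug attends over the cell:
   ``Gi' = CA(Gi, D)``, ``Dk' = CA(Dk, Gi)``;
2. drug-drug exchange in both directions with shared parameters:
   ``DA = CA(DA', DB')`` and ``DB = CA(DB', DA')``;
3. prediction head — mean-pool every entity, concatenate in the order
   ``Gi || DA || DB`` and apply an MLP with a final Tanh.

``CA(X1, X2) = softmax((X1 WQ)(X2 WK)^T / sqrt(dk)) (X2 WV)`` per head,
heads concatenated and output-projected; multi-head self-attention is
the same operation with ``X1 = X2``.  Each attention is wrapped in a
residual connection and layer norm.  The concatenation-plus-MLP variant
(:func:`mlp_fusion`) skips the exchanges entirely, matching the simpler
backbones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import MLP, LayerNorm, Linear, Module, Tensor, concatenate, softmax

__all__ = [
    "MultiHeadAttention",
    "FusionState",
    "BranchPrediction",
    "cross_attention",
    "multihead_self_attention",
    "ExchangeBlock",
    "drug_cell_exchange",
    "drug_drug_exchange",
    "PredictionHead",
    "predict_head",
    "mlp_fusion",
    "pool",
]


class MultiHeadAttention(Module):
    """Projection parameters for multi-head scaled dot-product attention."""

    def __init__(self, d_model: int, n_heads: int,
                 rng: np.random.Generator | None = None):
        if d_model % n_heads:
            raise ValueError(
                f"d_model={d_model} must be divisible by n_heads={n_heads}"
            )
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model
        self.n_heads = n_heads
        self.dk = d_model // n_heads
        self.WQ = Linear(d_model, d_model, rng, bias=False)
        self.WK = Linear(d_model, d_model, rng, bias=False)
        self.WV = Linear(d_model, d_model, rng, bias=False)
        self.WO = Linear(d_model, d_model, rng, bias=False)

    def _split(self, x: Tensor) -> Tensor:
        L = x.shape[0]
        return x.reshape(L, self.n_heads, self.dk).transpose(1, 0, 2)

    def attend(self, X1: Tensor, X2: Tensor,
               kv_mask: np.ndarray | None = None,
               return_weights: bool = False):
        if X1.shape[-1] != self.d_model or X2.shape[-1] != self.d_model:
            raise ValueError("input feature dimension does not match d_model")
        Q = self._split(self.WQ(X1))                    # (H, L1, dk)
        K = self._split(self.WK(X2))                    # (H, L2, dk)
        V = self._split(self.WV(X2))
        scores = (Q @ K.swapaxes(1, 2)) * (1.0 / np.sqrt(self.dk))
        mask = None if kv_mask is None else np.broadcast_to(
            kv_mask[None, None, :], scores.shape)
        weights = softmax(scores, axis=-1, mask=mask)
        out = weights @ V                               # (H, L1, dk)
        L1 = X1.shape[0]
        out = self.WO(out.transpose(1, 0, 2).reshape(L1, self.d_model))
        if return_weights:
            return out, weights
        return out


def cross_attention(X1: Tensor | np.ndarray, X2: Tensor | np.ndarray,
                    params: MultiHeadAttention,
                    kv_mask: np.ndarray | None = None,
                    return_weights: bool = False):
    """CA(X1, X2): X1 queries attend over X2 keys/values."""
    X1 = X1 if isinstance(X1, Tensor) else Tensor(X1)
    X2 = X2 if isinstance(X2, Tensor) else Tensor(X2)
    return params.attend(X1, X2, kv_mask=kv_mask, return_weights=return_weights)


def multihead_self_attention(X: Tensor | np.ndarray, params: MultiHeadAttention,
                             kv_mask: np.ndarray | None = None,
                             return_weights: bool = False):
    """MSA(X) = CA(X, X)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return params.attend(X, X, kv_mask=kv_mask, return_weights=return_weights)


@dataclass
class FusionState:
    Gi_prime: Tensor
    DA_prime: Tensor
    DB_prime: Tensor
    DA: Tensor | None = None
    DB: Tensor | None = None


class ExchangeBlock(Module):
    """One drug-cell + drug-drug exchange with residual + layer norm."""

    def __init__(self, d_model: int, n_heads: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cell_over_drugs = MultiHeadAttention(d_model, n_heads, rng)
        self.drug_over_cell = MultiHeadAttention(d_model, n_heads, rng)
        self.drug_over_drug = MultiHeadAttention(d_model, n_heads, rng)
        self.ln_cell = LayerNorm(d_model)
        self.ln_drug = LayerNorm(d_model)
        self.ln_pair = LayerNorm(d_model)

    def exchange_drug_cell(self, Gi: Tensor, DA: Tensor, DB: Tensor) -> FusionState:
        D = concatenate([DA, DB], axis=0)
        Gi_p = self.ln_cell(Gi + self.cell_over_drugs.attend(Gi, D))
        DA_p = self.ln_drug(DA + self.drug_over_cell.attend(DA, Gi))
        DB_p = self.ln_drug(DB + self.drug_over_cell.attend(DB, Gi))
        return FusionState(Gi_prime=Gi_p, DA_prime=DA_p, DB_prime=DB_p)

    def exchange_drug_drug(self, state: FusionState) -> FusionState:
        DA_p, DB_p = state.DA_prime, state.DB_prime
        # shared parameters in both directions: swapping inputs swaps outputs
        state.DA = self.ln_pair(DA_p + self.drug_over_drug.attend(DA_p, DB_p))
        state.DB = self.ln_pair(DB_p + self.drug_over_drug.attend(DB_p, DA_p))
        return state

    def __call__(self, Gi: Tensor, DA: Tensor, DB: Tensor) -> FusionState:
        return self.exchange_drug_drug(self.exchange_drug_cell(Gi, DA, DB))


def drug_cell_exchange(Gi, DA, DB, block: ExchangeBlock) -> FusionState:
    for name, x in (("Gi", Gi), ("DA", DA), ("DB", DB)):
        if x is None:
            raise ValueError(f"missing input {name}")
    lift = lambda x: x if isinstance(x, Tensor) else Tensor(x)  # noqa: E731
    return block.exchange_drug_cell(lift(Gi), lift(DA), lift(DB))


def drug_drug_exchange(DA_prime, DB_prime, block: ExchangeBlock) -> tuple[Tensor, Tensor]:
    if DA_prime is None or DB_prime is None:
        raise ValueError("both updated drug representations are required")
    lift = lambda x: x if isinstance(x, Tensor) else Tensor(x)  # noqa: E731
    state = FusionState(Gi_prime=None, DA_prime=lift(DA_prime), DB_prime=lift(DB_prime))
    state = block.exchange_drug_drug(state)
    return state.DA, state.DB


@dataclass
class BranchPrediction:
    Yi: float | np.ndarray
    branch: str

    def __post_init__(self) -> None:
        if self.branch not in ("causal", "trivial"):
            raise ValueError("branch must be 'causal' or 'trivial'")


def pool(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Mean-pool a (positions, d) matrix to a (d,) vector."""
    if x.ndim == 1:
        return x
    if mask is not None and not mask.all():
        keep = np.flatnonzero(mask)
        x = x[keep]
    return x.mean(axis=0)


class PredictionHead(Module):
    """MLP on the pooled concatenation ``Gi || DA || DB``, final Tanh."""

    def __init__(self, d_cell: int, d_drug: int, hidden: tuple[int, ...] = (128, 64),
                 rng: np.random.Generator | None = None, activation: str = "relu"):
        rng = rng or np.random.default_rng(0)
        self.mlp = MLP(d_cell + 2 * d_drug, list(hidden), 1, rng,
                       activation=activation)

    def __call__(self, z: Tensor) -> Tensor:
        return self.mlp(z).tanh()


def predict_head(Gi, DA, DB, head: PredictionHead, branch: str = "causal",
                 masks: tuple | None = None) -> BranchPrediction:
    """Pool each entity, concatenate in the printed order and predict."""
    lift = lambda x: x if isinstance(x, Tensor) else Tensor(x)  # noqa: E731
    parts = [Gi, DA, DB]
    pooled = [pool(lift(p), None if masks is None else masks[i])
              for i, p in enumerate(parts)]
    for p in pooled:
        if not np.isfinite(p.data).all():
            raise FloatingPointError("non-finite input to the prediction head")
    z = concatenate(pooled, axis=0).reshape(1, -1)
    y = head(z)
    return BranchPrediction(Yi=float(y.data[0, 0]), branch=branch)


def mlp_fusion(Gi, DA, DB, head: PredictionHead, branch: str = "causal",
               masks: tuple | None = None) -> BranchPrediction:
    """Concatenation + MLP fusion: the no-attention pathway."""
    return predict_head(Gi, DA, DB, head, branch=branch, masks=masks)
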