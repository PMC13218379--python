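"""Causal mask encoder: learnable complementary soft masks over genes.

Given a cell-line profile ``C`` (F omic layers x N genes), a shared
fully-connected map turns each gene's F-dimensional omics column into a
learned feature ``g_i``; a two-channel projection followed by a softmax
over the two channels yields per-gene attention weights
``(alpha_c_i, alpha_t_i)`` with ``alpha_c_i + alpha_t_i = 1`` by
construction.  Stacking the channels over genes gives the *causal
awareness mask* ``Mc`` and *trivial awareness mask* ``Mt = 1 - Mc``,
and the disentangled profiles are the Hadamard products
``Gc = C (.) Mc`` and ``Gt = C (.) Mt`` (so ``Gc + Gt = C`` exactly).

The per-gene map is parameter-shared across genes: attribution stays
traceable to individual genes, and the parameter count is independent
of the panel size.  ``alpha_c_i`` is the gene's *causal score* in that
cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Linear, Module, Parameter, Tensor, softmax

from .synthdata import CellProfile  # canonical profile container  # noqa: F401

__all__ = [
    "GeneFeatures",
    "MaskPair",
    "MaskedProfiles",
    "MaskEncoder",
    "extract_gene_features",
    "gene_attention",
    "apply_masks",
    "complement_mask",
]


@dataclass
class GeneFeatures:
    """Per-gene learned features: row i is g_i, shape (N, d_g)."""

    g: Tensor

    def __post_init__(self) -> None:
        if not np.isfinite(self.g.data).all():
            raise ValueError("gene features contain non-finite values")


@dataclass
class MaskPair:
    alpha_c: Tensor     # (N,)
    alpha_t: Tensor     # (N,)
    Mc: Tensor          # (N,)
    Mt: Tensor          # (N,)

    def __post_init__(self) -> None:
        s = self.alpha_c.data + self.alpha_t.data
        if not np.allclose(s, 1.0, atol=1e-6):
            raise ValueError("attention channels must sum to 1 per gene")


@dataclass
class MaskedProfiles:
    Gc: Tensor          # (F, N)
    Gt: Tensor          # (F, N)


class MaskEncoder(Module):
    """Per-gene two-channel attention head over learned gene features.

    The feature map is parameter-shared across genes (gene i's feature
    comes from its own F-vector), keeping attribution traceable to
    individual genes.  When the gene panel is known (``n_genes`` given),
    each gene additionally carries a learnable two-channel logit bias:
    the shared map captures how a gene's *value* modulates its score
    within a cell line, while the bias captures the gene's panel-wide
    propensity to be causal — without it, two genes with identical
    value distributions could never be told apart.
    """

    def __init__(self, n_omics: int, d_g: int = 32,
                 rng: np.random.Generator | None = None, bias: bool = False,
                 n_genes: int | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_omics = n_omics
        self.d_g = d_g
        self.fc = Linear(n_omics, d_g, rng)
        self.W = Linear(d_g, 2, rng, bias=bias)
        self.gene_bias = (Parameter(np.zeros((n_genes, 2)))
                          if n_genes is not None else None)

    def gene_features(self, C: Tensor | np.ndarray) -> GeneFeatures:
        C = C if isinstance(C, Tensor) else Tensor(C)
        if C.ndim != 2 or C.shape[0] != self.n_omics:
            raise ValueError(
                f"profile must be ({self.n_omics}, N); got {C.shape}"
            )
        cols = C.T                                   # (N, F): one row per gene
        return GeneFeatures(g=self.fc(cols).tanh())

    def attention(self, feats: GeneFeatures) -> MaskPair:
        logits = self.W(feats.g)                     # (N, 2)
        if self.gene_bias is not None:
            if feats.g.shape[0] != self.gene_bias.shape[0]:
                raise ValueError("gene count does not match the panel bias")
            logits = logits + self.gene_bias
        if not np.isfinite(logits.data).all():
            bad = int(np.argwhere(~np.isfinite(logits.data))[0][0])
            raise FloatingPointError(f"non-finite attention logits at gene index {bad}")
        alpha = softmax(logits, axis=-1)
        ac, at = alpha[:, 0], alpha[:, 1]
        return MaskPair(alpha_c=ac, alpha_t=at, Mc=ac, Mt=at)

    def __call__(self, C: Tensor | np.ndarray) -> tuple[MaskPair, MaskedProfiles]:
        C = C if isinstance(C, Tensor) else Tensor(C)
        mask = self.attention(self.gene_features(C))
        return mask, apply_masks(C, mask)


def extract_gene_features(C: Tensor | np.ndarray, encoder: MaskEncoder) -> GeneFeatures:
    return encoder.gene_features(C)


def gene_attention(feats: GeneFeatures, encoder: MaskEncoder) -> MaskPair:
    return encoder.attention(feats)


def apply_masks(C: Tensor | np.ndarray, mask: MaskPair) -> MaskedProfiles:
    """Hadamard-mask the profile with each channel, broadcast over omic rows."""
    C = C if isinstance(C, Tensor) else Tensor(C)
    n = mask.Mc.shape[0]
    if C.shape[1] != n:
        raise ValueError(f"mask length {n} does not match gene axis {C.shape[1]}")
    Gc = C * mask.Mc.reshape(1, n)
    Gt = C * mask.Mt.reshape(1, n)
    return MaskedProfiles(Gc=Gc, Gt=Gt)


def complement_mask(M: np.ndarray) -> np.ndarray:
    """The complementary soft mask 1_N - M."""
    M = np.asarray(M, dtype=np.float64)
    if ((M < 0) | (M > 1)).any():
        raise ValueError("mask entries must lie in [0, 1]")
    return 1.0 - M
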