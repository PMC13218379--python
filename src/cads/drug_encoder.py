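"""Drug feature extraction: SMILES to learnable representations.

Two pathways mirror the two families of synergy backbones:

* **Sequence** — the SMILES string is segmented into chemically
  meaningful tokens (multi-character atoms, bracket atoms, ring digits,
  bond symbols), embedded, combined with a unit-norm sinusoidal
  positional encoding and layer-normalized per position:
  ``D = LN(T (+) P)``.
* **2D graph** — the SMILES is parsed with RDKit into an atom/bond
  graph and encoded by a graph-attention layer followed by graph
  convolutions, then mean-pooled to a drug vector: ``D = GCN(GAT(V, E))``.

Both produce a :class:`DrugEmbedding`; which one a model uses is a
backbone choice, not a property of the drug.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Linear, Module, Parameter, Tensor, glorot, layer_norm, softmax

__all__ = [
    "SmilesParseError",
    "Vocabulary",
    "TokenSequence",
    "PositionalEncoding",
    "MolecularGraph",
    "DrugEmbedding",
    "tokenize_smiles",
    "build_vocab",
    "SequenceEncoder",
    "encode_sequence",
    "build_graph",
    "GraphEncoder",
    "encode_graph",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized or parsed."""


# Multi-character atoms first so "Cl"/"Br" never split into C+l / B+r.
_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|Si|Se|%\d{2}|[A-Za-z]|\d|[=#\$:/\\\.\-\+\(\)@\*~])"
)

PAD, UNK = "<pad>", "<unk>"


@dataclass
class Vocabulary:
    """Token-to-index mapping with PAD at 0 and an optional UNK."""

    tokens: list[str]
    has_unk: bool = True

    def __post_init__(self) -> None:
        base = [PAD] + ([UNK] if self.has_unk else [])
        self._index = {t: i for i, t in enumerate(base + list(self.tokens))}
        self.all_tokens = base + list(self.tokens)

    def __len__(self) -> int:
        return len(self.all_tokens)

    def index(self, token: str) -> int:
        idx = self._index.get(token)
        if idx is None:
            if self.has_unk:
                return self._index[UNK]
            raise SmilesParseError(f"token {token!r} not in vocabulary and no UNK configured")
        return idx

    def decode(self, indices) -> list[str]:
        return [self.all_tokens[i] for i in indices if self.all_tokens[i] != PAD]

    def to_json(self) -> str:
        return json.dumps({"tokens": self.tokens, "has_unk": self.has_unk})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(tokens=d["tokens"], has_unk=d["has_unk"])


@dataclass
class TokenSequence:
    tokens: np.ndarray          # (max_len,) int indices, PAD-padded
    length: int
    pad_mask: np.ndarray        # (max_len,) bool, True where real token

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("token sequence must contain at least one token")


def split_smiles(smiles: str) -> list[str]:
    """Segment a SMILES string into tokens; total on its grammar."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        residue = re.sub(_TOKEN_RE, "", smiles)
        raise SmilesParseError(f"cannot tokenize {smiles!r}: unrecognized {residue!r}")
    return tokens


def build_vocab(smiles_list, has_unk: bool = True) -> Vocabulary:
    seen: dict[str, None] = {}
    for s in smiles_list:
        for t in split_smiles(s):
            seen.setdefault(t)
    return Vocabulary(tokens=list(seen), has_unk=has_unk)


def tokenize_smiles(smiles: str, vocab: Vocabulary, max_len: int = 128) -> TokenSequence:
    """Deterministic tokenization to a padded index sequence."""
    toks = split_smiles(smiles)[:max_len]
    idx = np.zeros(max_len, dtype=np.int64)
    for i, t in enumerate(toks):
        idx[i] = vocab.index(t)
    mask = np.zeros(max_len, dtype=bool)
    mask[: len(toks)] = True
    return TokenSequence(tokens=idx, length=len(toks), pad_mask=mask)


def detokenize(seq: TokenSequence, vocab: Vocabulary) -> str:
    return "".join(vocab.decode(seq.tokens[: seq.length]))


@dataclass
class PositionalEncoding:
    """Sinusoidal positional encoding with every row rescaled to unit
    L2 norm (the model's stated constraint ||P_i||_2 = 1)."""

    max_len: int
    d_model: int
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pos = np.arange(self.max_len)[:, None]
        i = np.arange(self.d_model)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / self.d_model)
        P = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        self.P = P
        assert np.allclose(np.linalg.norm(self.P, axis=1), 1.0, atol=1e-6)


@dataclass
class DrugEmbedding:
    """Encoded drug: per-position matrix plus its validity mask."""

    Dk: np.ndarray | Tensor     # (positions, d_model)
    pad_mask: np.ndarray | None = None

    def pooled(self) -> np.ndarray:
        D = self.Dk.data if isinstance(self.Dk, Tensor) else self.Dk
        if self.pad_mask is None:
            return D.mean(axis=0)
        return D[self.pad_mask].mean(axis=0)


class SequenceEncoder(Module):
    """Token embedding (+) positional encoding, layer-normalized.

    ``combine`` is "add" (default) or "concat"; with "concat" the joined
    vector is projected back to ``d_model``.
    """

    def __init__(self, vocab: Vocabulary, d_model: int, max_len: int = 128,
                 rng: np.random.Generator | None = None, combine: str = "add"):
        if combine not in ("add", "concat"):
            raise ValueError("combine must be 'add' or 'concat'")
        rng = rng or np.random.default_rng(0)
        self.vocab = vocab
        self.d_model = d_model
        self.max_len = max_len
        self.combine = combine
        self.embedding = Parameter(glorot(rng, len(vocab), d_model))
        self.pos = PositionalEncoding(max_len, d_model)
        if combine == "concat":
            self.proj = Linear(2 * d_model, d_model, rng)

    def __call__(self, seq: TokenSequence) -> DrugEmbedding:
        L = seq.length
        T = self.embedding[seq.tokens[:L]]
        P = Tensor(self.pos.P[:L])
        if self.combine == "add":
            x = T + P
        else:
            from ._tensor import concatenate

            x = self.proj(concatenate([T, P], axis=-1))
        out = layer_norm(x)                 # per-position, pre-affine
        return DrugEmbedding(Dk=out, pad_mask=np.ones(L, dtype=bool))


def encode_sequence(seq: TokenSequence, encoder: SequenceEncoder) -> DrugEmbedding:
    if seq.length > encoder.max_len:
        raise ValueError("sequence longer than the encoder's max_len")
    return encoder(seq)


# --------------------------------------------------------------------------
# 2D molecular graphs
# --------------------------------------------------------------------------

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
_MAX_DEGREE = 5
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1
_BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]


@dataclass
class MolecularGraph:
    atoms: np.ndarray                      # (n_atoms, ATOM_FEATURE_DIM)
    bonds: list[tuple[int, int]]           # each undirected bond once
    bond_features: np.ndarray              # (n_bonds, len(_BOND_TYPES))

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A


def _atom_features(atom) -> np.ndarray:
    f = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    f[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    deg = min(atom.GetDegree(), _MAX_DEGREE)
    f[len(_ELEMENTS) + 1 + deg] = 1.0
    f[-1] = float(atom.GetIsAromatic())
    return f


def build_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into an atom/bond graph via RDKit."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"RDKit could not parse SMILES {smiles!r}")
    atoms = np.stack([_atom_features(a) for a in mol.GetAtoms()]) \
        if mol.GetNumAtoms() else np.zeros((0, ATOM_FEATURE_DIM))
    bonds, bf = [], []
    for b in mol.GetBonds():
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        onehot = np.zeros(len(_BOND_TYPES))
        name = str(b.GetBondType())
        if name in _BOND_TYPES:
            onehot[_BOND_TYPES.index(name)] = 1.0
        bf.append(onehot)
    bf_arr = np.stack(bf) if bf else np.zeros((0, len(_BOND_TYPES)))
    return MolecularGraph(atoms=atoms, bonds=bonds, bond_features=bf_arr)


class GraphEncoder(Module):
    """One graph-attention layer cascaded into graph convolutions.

    The attention layer (multi-head, adjacency-masked, self-loops
    included) captures local structure; the convolution layers with
    symmetric-normalized adjacency propagate it globally.  Global mean
    pooling yields a permutation-invariant drug vector.
    """

    def __init__(self, d_in: int = ATOM_FEATURE_DIM, d_hidden: int = 64,
                 d_out: int = 64, n_heads: int = 4, n_gcn: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if d_hidden % n_heads:
            raise ValueError("d_hidden must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_hidden // n_heads
        self.Wgat = Parameter(glorot(rng, d_in, d_hidden))
        self.a_src = Parameter(glorot(rng, self.d_head, n_heads, shape=(n_heads, self.d_head)))
        self.a_dst = Parameter(glorot(rng, self.d_head, n_heads, shape=(n_heads, self.d_head)))
        dims = [d_hidden] * n_gcn + [d_out]
        self.gcn = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def _gat(self, X: Tensor, A: np.ndarray) -> Tensor:
        n = A.shape[0]
        H = (X @ self.Wgat).reshape(n, self.n_heads, self.d_head)
        Hh = H.transpose(1, 0, 2)                          # (heads, n, d_head)
        src = (Hh * self.a_src.reshape(self.n_heads, 1, self.d_head)).sum(axis=-1)
        dst = (Hh * self.a_dst.reshape(self.n_heads, 1, self.d_head)).sum(axis=-1)
        e = src.reshape(self.n_heads, n, 1) + dst.reshape(self.n_heads, 1, n)
        e = e.relu() - (-e).relu() * 0.2                   # LeakyReLU(0.2)
        mask = (A + np.eye(n)) > 0
        alpha = softmax(e, axis=-1, mask=mask[None, :, :])
        out = alpha @ Hh                                   # (heads, n, d_head)
        return out.transpose(1, 0, 2).reshape(n, self.n_heads * self.d_head).relu()

    def __call__(self, graph: MolecularGraph) -> DrugEmbedding:
        if graph.n_atoms == 0:
            raise ValueError("cannot encode an empty molecular graph")
        A = graph.adjacency()
        H = self._gat(Tensor(graph.atoms), A)
        Ahat = A + np.eye(graph.n_atoms)
        d = Ahat.sum(axis=1)
        norm = Tensor(Ahat / np.sqrt(np.outer(d, d)))
        for i, layer in enumerate(self.gcn):
            H = layer(norm @ H)
            if i < len(self.gcn) - 1:
                H = H.relu()
        return DrugEmbedding(Dk=H, pad_mask=np.ones(graph.n_atoms, dtype=bool))


def encode_graph(graph: MolecularGraph, encoder: GraphEncoder) -> DrugEmbedding:
    return encoder(graph)
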