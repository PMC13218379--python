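"""Synthetic drug-synergy datasets with a planted causal gene structure.

Real synergy panels never reveal which genes actually drive a drug
pair's interaction, so claims about causal-gene recovery cannot be
scored on them.  This module builds datasets where the ground truth is
known by construction: a small set of *causal* genes carries all of the
label signal, each causal gene is paired with a correlated *decoy*
(trivial) gene that is confounded with it but carries no independent
effect, and every remaining gene is pure noise.

Generative model
----------------
* Gene values: gene ``g`` has a location ``mu_g ~ N(0, 1)`` and scale
  ``sigma_g ~ U(0.5, 1.5)``; cell ``c``'s layer-1 value is
  ``x_{c,g} ~ N(mu_g, sigma_g^2)``.  Omics layers beyond the first are
  noisy copies of layer 1 with correlation 0.7 and the same marginal.
* Decoys: the decoy paired with causal gene ``g`` has layer-1 z-score
  ``z_d = rho * z_g + sqrt(1 - rho^2) * eps``, giving population
  correlation exactly ``confound_rho`` with its causal partner.
* Drugs: each drug carries a latent vector ``u ~ N(0, I_{d_lat})`` and a
  distinct small valid SMILES string; the pair interaction is the
  symmetric dot product ``s(A, B) = u_A . u_B``.
* Labels: ``y = s(A, B) * sum_{g in causal} w_g * xbar_{c,g} + eps``
  with ``w_g ~ +-U(0.5, 1.5)``, ``xbar`` the omics-averaged gene value
  and ``eps ~ N(0, noise_sd^2)``.  Labels are then standardized to zero
  mean / unit variance; the transform is stored so predictions can be
  mapped back to the original scale.

Everything is driven by a single root seed split per step, so the same
seed reproduces the same dataset bit-for-bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellProfile",
    "DrugRecord",
    "SynergyExample",
    "SyntheticTruth",
    "Standardization",
    "SyntheticDataset",
    "SCORE_TYPES",
    "SMILES_POOL",
    "generate_profiles",
    "plant_truth",
    "generate_drugs",
    "generate_labels",
    "simulate",
]

SCORE_TYPES = ("loewe", "hsa", "bliss", "zip", "s_score")

# Distinct, small, chemically valid SMILES used for synthetic drugs so
# that both the sequence and the graph encoder run without a corpus.
SMILES_POOL: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC",
    "CO", "CCO", "CCCO", "CCCCO", "CN", "CCN", "CCCN",
    "C=C", "CC=C", "C#N", "CC#N", "C=O", "CC=O", "CCC=O",
    "COC", "CCOC", "CNC", "CCNC", "CS", "CCS", "CSC",
    "CCl", "CCCl", "CBr", "CCBr", "CF", "CCF", "FC(F)F",
    "CC(C)C", "CC(C)O", "CC(C)N", "CC(=O)O", "CC(=O)N", "OC=O",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "OCc1ccccc1", "c1ccncc1", "Cc1ccncc1",
    "c1ccsc1", "c1ccoc1", "c1cc[nH]c1", "Clc1ccccc1",
)


@dataclass
class CellProfile:
    """Omics profile of one cell line: ``C`` is F omic layers x N genes."""

    cell_id: str
    C: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2:
            raise ValueError("profile matrix must be 2-D (omics x genes)")
        if self.C.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match the gene axis")
        if not np.isfinite(self.C).all():
            raise ValueError(f"profile {self.cell_id} contains non-finite values")


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass
class SynergyExample:
    drug_a_id: str
    drug_b_id: str
    cell_id: str
    score_type: str
    y: float

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"unknown score_type {self.score_type!r}")
        if not np.isfinite(self.y):
            raise ValueError("synergy value must be finite")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    causal_genes: tuple[int, ...]
    decoy_genes: tuple[int, ...]          # decoy_genes[i] pairs causal_genes[i]
    gene_effects: dict[int, float]        # causal gene index -> weight w_g
    drug_latents: dict[str, np.ndarray]
    noise_sd: float
    confound_rho: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.confound_rho < 1):
            raise ValueError("confound_rho must lie in [0, 1)")
        if any(w == 0 for w in self.gene_effects.values()):
            raise ValueError("every causal gene effect must be nonzero")
        if len(self.decoy_genes) != len(self.causal_genes):
            raise ValueError("each causal gene needs exactly one decoy")


@dataclass
class Standardization:
    """Affine label transform ``z = (y - mean) / sd`` and its inverse."""

    mean: float
    sd: float

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=np.float64) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=np.float64) * self.sd + self.mean


@dataclass
class SyntheticDataset:
    profiles: list[CellProfile]
    drugs: list[DrugRecord]
    examples: list[SynergyExample]
    truth: SyntheticTruth | None
    standardization: Standardization
    gene_loc: np.ndarray = field(default_factory=lambda: np.array([]))
    gene_scale: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def gene_ids(self) -> list[str]:
        return self.profiles[0].gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i + 1:0{width}d}" for i in range(n_genes)]


def _drug_ids(n_drugs: int) -> list[str]:
    width = max(3, len(str(n_drugs)))
    return [f"drug{i + 1:0{width}d}" for i in range(n_drugs)]


def generate_profiles(
    n_cells: int,
    n_genes: int,
    n_omics: int = 1,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> list[CellProfile]:
    """Draw per-cell omics matrices from the stated per-gene distribution.

    If ``truth`` is given, each decoy gene's layer-1 z-scores are rebuilt
    as ``rho * z_causal + sqrt(1 - rho^2) * eps`` so that the decoy is
    confounded with its causal partner at correlation ``confound_rho``.
    """
    if n_cells < 1 or n_genes < 2 or n_omics < 1:
        raise ValueError(
            f"invalid dimensions: n_cells={n_cells}, n_genes={n_genes}, n_omics={n_omics}"
        )
    root = np.random.SeedSequence(seed)
    rng_param, rng_layer1, rng_decoy, rng_extra = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    mu = rng_param.normal(0.0, 1.0, size=n_genes)
    sigma = rng_param.uniform(0.5, 1.5, size=n_genes)
    z1 = rng_layer1.normal(size=(n_cells, n_genes))
    if truth is not None:
        rho = truth.confound_rho
        eps = rng_decoy.normal(size=(n_cells, len(truth.decoy_genes)))
        for j, (d, c) in enumerate(zip(truth.decoy_genes, truth.causal_genes)):
            z1[:, d] = rho * z1[:, c] + np.sqrt(1.0 - rho**2) * eps[:, j]
    layers = [mu + sigma * z1]
    for _ in range(1, n_omics):
        # noisy copy of layer 1: same marginal, correlation 0.7
        e = rng_extra.normal(size=(n_cells, n_genes))
        layers.append(mu + sigma * (0.7 * z1 + np.sqrt(1.0 - 0.49) * e))
    ids = _gene_ids(n_genes)
    cells = []
    for c in range(n_cells):
        C = np.stack([layer[c] for layer in layers], axis=0)
        cells.append(CellProfile(cell_id=f"cell{c + 1:04d}", C=C, gene_ids=ids))
    return cells


def generating_params(n_genes: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (location, scale) used by :func:`generate_profiles` for
    this seed — the closed-form reference for distribution checks."""
    rng_param = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[0])
    mu = rng_param.normal(0.0, 1.0, size=n_genes)
    sigma = rng_param.uniform(0.5, 1.5, size=n_genes)
    return mu, sigma


def plant_truth(
    n_genes: int,
    k_causal: int,
    n_drugs: int,
    d_lat: int = 8,
    noise_sd: float = 0.3,
    confound_rho: float = 0.6,
    seed: int = 0,
) -> SyntheticTruth:
    """Sample the causal gene set, paired decoys, effects and drug latents."""
    if not (0 <= k_causal <= n_genes / 2):
        raise ValueError(
            f"k_causal={k_causal} must leave room for paired decoys (<= n_genes/2)"
        )
    if d_lat < 1:
        raise ValueError("d_lat must be >= 1")
    root = np.random.SeedSequence(seed)
    rng_genes, rng_w, rng_lat = (np.random.default_rng(s) for s in root.spawn(3))
    perm = rng_genes.permutation(n_genes)
    causal = tuple(int(i) for i in sorted(perm[:k_causal]))
    decoys = tuple(int(i) for i in perm[k_causal:2 * k_causal])
    signs = rng_w.choice([-1.0, 1.0], size=k_causal)
    mags = rng_w.uniform(0.5, 1.5, size=k_causal)
    effects = {g: float(s * m) for g, s, m in zip(causal, signs, mags)}
    latents = {
        did: rng_lat.normal(size=d_lat) for did in _drug_ids(n_drugs)
    }
    return SyntheticTruth(
        causal_genes=causal,
        decoy_genes=decoys,
        gene_effects=effects,
        drug_latents=latents,
        noise_sd=float(noise_sd),
        confound_rho=float(confound_rho),
        seed=seed,
    )


def generate_drugs(n_drugs: int, seed: int = 0) -> list[DrugRecord]:
    """Assign each synthetic drug a small valid SMILES string.

    Drugs get distinct SMILES whenever the pool allows (sampling without
    replacement), so a drug's identity is recoverable from its structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if n_drugs <= len(SMILES_POOL):
        smiles = rng.choice(len(SMILES_POOL), size=n_drugs, replace=False)
    else:
        smiles = rng.choice(len(SMILES_POOL), size=n_drugs, replace=True)
    return [
        DrugRecord(drug_id=did, smiles=SMILES_POOL[int(s)])
        for did, s in zip(_drug_ids(n_drugs), smiles)
    ]


def signal(truth: SyntheticTruth, profile: CellProfile,
           drug_a: str, drug_b: str) -> float:
    """Noise-free label: ``s(A,B) * sum_g w_g * xbar_{c,g}``."""
    xbar = profile.C.mean(axis=0)
    t = sum(w * xbar[g] for g, w in truth.gene_effects.items())
    s = float(truth.drug_latents[drug_a] @ truth.drug_latents[drug_b])
    return s * t


def generate_labels(
    profiles: list[CellProfile],
    drugs: list[DrugRecord],
    truth: SyntheticTruth,
    n_examples: int,
    seed: int = 0,
    score_type: str = "s_score",
) -> tuple[list[SynergyExample], Standardization]:
    """Sample (drug pair, cell) uniformly and emit standardized labels."""
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    if profiles and truth.causal_genes and max(truth.causal_genes) >= profiles[0].C.shape[1]:
        raise ValueError("truth refers to genes outside the profiles' panel")
    root = np.random.SeedSequence(seed)
    rng_pick, rng_noise = (np.random.default_rng(s) for s in root.spawn(2))
    pairs = list(itertools.combinations(range(len(drugs)), 2))
    pair_idx = rng_pick.integers(0, len(pairs), size=n_examples)
    cell_idx = rng_pick.integers(0, len(profiles), size=n_examples)
    noise = rng_noise.normal(0.0, truth.noise_sd, size=n_examples)
    raw = np.empty(n_examples)
    records = []
    for i in range(n_examples):
        a, b = pairs[pair_idx[i]]
        prof = profiles[cell_idx[i]]
        raw[i] = signal(truth, prof, drugs[a].drug_id, drugs[b].drug_id) + noise[i]
        records.append((drugs[a].drug_id, drugs[b].drug_id, prof.cell_id))
    sd = float(raw.std())
    std = Standardization(mean=float(raw.mean()), sd=sd if sd > 0 else 1.0)
    z = std.apply(raw)
    examples = [
        SynergyExample(a, b, c, score_type, float(z[i]))
        for i, (a, b, c) in enumerate(records)
    ]
    return examples, std


def simulate(
    n_cells: int = 60,
    n_genes: int = 300,
    k_causal: int = 15,
    n_drugs: int = 30,
    n_omics: int = 1,
    d_lat: int = 8,
    noise_sd: float = 0.3,
    confound_rho: float = 0.6,
    n_examples: int = 6000,
    seed: int = 0,
    score_type: str = "s_score",
) -> SyntheticDataset:
    """Build a complete synthetic dataset (the package's default study
    conditions) from a single root seed."""
    root = np.random.SeedSequence(seed)
    s_truth, s_prof, s_drug, s_lab = (int(s.generate_state(1)[0] % (2**31))
                                      for s in root.spawn(4))
    truth = plant_truth(n_genes, k_causal, n_drugs, d_lat=d_lat,
                        noise_sd=noise_sd, confound_rho=confound_rho, seed=s_truth)
    profiles = generate_profiles(n_cells, n_genes, n_omics, seed=s_prof, truth=truth)
    drugs = generate_drugs(n_drugs, seed=s_drug)
    examples, std = generate_labels(profiles, drugs, truth, n_examples,
                                    seed=s_lab, score_type=score_type)
    loc, scale = generating_params(n_genes, s_prof)
    return SyntheticDataset(profiles=profiles, drugs=drugs, examples=examples,
                            truth=truth, standardization=std,
                            gene_loc=loc, gene_scale=scale)
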