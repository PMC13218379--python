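"""Evaluation and interpretability procedures for the dual-branch model.

Covers the analyses a synergy-prediction study runs after training:
standard regression metrics; causal/trivial top-gene ablation; few-shot
robustness curves with fitted slopes; pooled causal-score statistics
across cells and replicate runs; mean within-class distance of cell
embeddings; and Integrated Gradients attribution of the causal branch
with respect to the raw omics profile.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tensor import Tensor
from .cads_model import TrainConfig, TrainedModel, forward, split_dataset, train

__all__ = [
    "MetricsReport",
    "AblationResult",
    "FewShotFit",
    "CausalScoreStats",
    "regression_metrics",
    "mean_causal_scores",
    "ablate_top_genes",
    "fewshot_curve",
    "causal_score_stats",
    "within_class_distance",
    "integrated_gradients",
    "attribute_example",
    "causal_gene_auroc",
]

METRIC_NAMES = ("MAE", "RMSE", "R2", "PCC")


@dataclass
class MetricsReport:
    MAE: float
    RMSE: float
    R2: float | None
    PCC: float | None
    n: int
    split: str = ""
    degenerate: str | None = None   # set when R2/PCC are undefined

    def __post_init__(self) -> None:
        if self.MAE > self.RMSE + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")
        if self.R2 is not None and self.R2 > 1 + 1e-12:
            raise ValueError("R2 cannot exceed 1")
        if self.PCC is not None and abs(self.PCC) > 1 + 1e-12:
            raise ValueError("|PCC| cannot exceed 1")

    def as_dict(self) -> dict:
        return {"MAE": self.MAE, "RMSE": self.RMSE, "R2": self.R2,
                "PCC": self.PCC, "n": self.n, "split": self.split}


def regression_metrics(y_true, y_pred, split: str = "") -> MetricsReport:
    """MAE, RMSE, R2 and Pearson correlation with explicit degeneracy
    flags instead of silent NaNs."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("metrics require finite inputs")
    e = y_pred - y_true
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e**2).mean()))
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    degenerate = None
    if sst == 0.0:
        r2 = None
        degenerate = "zero variance in y_true"
    else:
        r2 = float(1.0 - (e**2).sum() / sst)
    if y_pred.std() == 0.0 or y_true.std() == 0.0:
        pcc = None
        degenerate = degenerate or "zero variance in one input"
    else:
        pcc = float(np.corrcoef(y_true, y_pred)[0, 1])
    return MetricsReport(MAE=mae, RMSE=rmse, R2=r2, PCC=pcc,
                         n=y_true.size, split=split, degenerate=degenerate)


# --------------------------------------------------------------------------
# causal / trivial gene ablation
# --------------------------------------------------------------------------

@dataclass
class AblationResult:
    branch: str
    k_masked: int
    before: MetricsReport
    after: MetricsReport
    loss: dict = field(default_factory=dict)  # per-metric degradation


def mean_causal_scores(trained: TrainedModel, dataset) -> np.ndarray:
    """Per-gene causal score alpha_c averaged over the cell panel."""
    C_all = np.stack([p.C for p in dataset.profiles])
    ac, _ = trained.model.masks_for_cells(C_all)
    return ac.data.mean(axis=0)


def ablate_top_genes(trained: TrainedModel, dataset, branch: str, k: int,
                     examples=None) -> AblationResult:
    """Zero the top-k genes of one attention ranking and re-evaluate.

    Genes are ranked by their run-mean attention weight (alpha_c for the
    causal branch, alpha_t for the trivial branch, ties broken by gene
    index); their columns in every profile are zeroed at inference and
    the regression metrics are recomputed on the evaluation examples.
    """
    if branch not in ("causal", "trivial"):
        raise ValueError("branch must be 'causal' or 'trivial'")
    n_genes = dataset.n_genes
    if not (0 <= k <= n_genes):
        raise ValueError(f"k={k} must lie in [0, {n_genes}]")
    if examples is None:
        if trained.split is None:
            raise ValueError("no evaluation examples given and no stored split")
        examples = [dataset.examples[i] for i in trained.split["test"]]
    scores = mean_causal_scores(trained, dataset)
    if branch == "trivial":
        scores = 1.0 - scores
    order = np.lexsort((np.arange(n_genes), -scores))  # ties -> lower index
    top = order[:k]
    y = np.array([e.y for e in examples])
    before = regression_metrics(y, forward(trained.model, dataset, examples).Yc,
                                split="test")
    ablated = copy.copy(dataset)
    ablated.profiles = [copy.copy(p) for p in dataset.profiles]
    for p in ablated.profiles:
        C = p.C.copy()
        C[:, top] = 0.0
        p.C = C
    after = regression_metrics(y, forward(trained.model, ablated, examples).Yc,
                               split="test")
    loss = {
        "MAE": after.MAE - before.MAE,
        "RMSE": after.RMSE - before.RMSE,
        "R2": None if (before.R2 is None or after.R2 is None)
        else before.R2 - after.R2,
        "PCC": None if (before.PCC is None or after.PCC is None)
        else before.PCC - after.PCC,
    }
    return AblationResult(branch=branch, k_masked=int(k), before=before,
                          after=after, loss=loss)


# --------------------------------------------------------------------------
# few-shot robustness
# --------------------------------------------------------------------------

@dataclass
class FewShotFit:
    fractions: list[float]
    metrics: dict            # model name -> fraction -> MetricsReport
    slopes: dict             # model name -> metric -> (k, b)


def fit_line(x, y) -> tuple[float, float]:
    """Exact least-squares line y = k x + b via the normal equations."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    A = np.stack([x, np.ones_like(x)], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fewshot_curve(dataset, fractions, configs: dict[str, TrainConfig],
                  seed: int = 0) -> FewShotFit:
    """Train each configuration on shrinking fractions of the training
    split and fit a performance-vs-fraction line per metric.

    The validation/test splits are fixed across fractions and models so
    that only the training budget varies.
    """
    fractions = [float(f) for f in fractions]
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    metrics: dict[str, dict[float, MetricsReport]] = {}
    slopes: dict[str, dict[str, tuple[float, float]]] = {}
    for name, config in configs.items():
        metrics[name] = {}
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]).generate_state(1)[0])
        # reference split from an untouched training run setup
        r_split = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
        tr, val, test = split_dataset(dataset, config, r_split)
        for frac in fractions:
            n_sub = int(round(frac * len(tr)))
            if n_sub < 1:
                raise ValueError(f"fraction {frac} yields an empty training set")
            sub = rng.choice(tr, size=n_sub, replace=False)
            trained = train(dataset, config, train_idx=sub)
            test_examples = [dataset.examples[i] for i in test]
            y = np.array([e.y for e in test_examples])
            pred = forward(trained.model, dataset, test_examples)
            metrics[name][frac] = regression_metrics(y, pred.Yc, split="test")
        slopes[name] = {}
        for m in METRIC_NAMES:
            vals = [getattr(metrics[name][f], m) for f in fractions]
            if any(v is None for v in vals):
                continue
            slopes[name][m] = fit_line(fractions, vals)
    return FewShotFit(fractions=fractions, metrics=metrics, slopes=slopes)


# --------------------------------------------------------------------------
# causal-score statistics across replicate runs
# --------------------------------------------------------------------------

@dataclass
class CausalScoreStats:
    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_obs: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "mean": self.mean,
                             "sd": self.sd})

    def ranked(self) -> pd.DataFrame:
        """Two-column ranked gene list (.rnk-style), highest mean first."""
        return self.table().sort_values("mean", ascending=False)[
            ["gene_id", "mean"]]


def causal_score_stats(mask_tables: list[np.ndarray],
                       gene_ids: list[str]) -> CausalScoreStats:
    """Per-gene pooled mean and standard deviation of causal scores
    across (cell, replicate-run) observations, accumulated with
    Welford's streaming update."""
    if not mask_tables:
        raise ValueError("at least one replicate mask table is required")
    n_genes = len(gene_ids)
    for t in mask_tables:
        if np.asarray(t).shape[1] != n_genes:
            raise ValueError("gene panel mismatch across replicate runs")
    count = 0
    mean = np.zeros(n_genes)
    m2 = np.zeros(n_genes)
    for t in mask_tables:
        for row in np.asarray(t, dtype=np.float64):
            count += 1
            delta = row - mean
            mean += delta / count
            m2 += delta * (row - mean)
    sd = np.sqrt(m2 / count) if count > 0 else np.zeros(n_genes)
    return CausalScoreStats(gene_ids=list(gene_ids), mean=mean, sd=sd,
                            n_obs=count)


# --------------------------------------------------------------------------
# embedding separability
# --------------------------------------------------------------------------

def within_class_distance(embeddings, labels) -> float:
    """Mean Euclidean distance of each point to its class centroid,
    averaged over all points."""
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    if X.size == 0:
        raise ValueError("empty embedding set")
    if X.ndim == 1:
        X = X[:, None]
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        centroid = pts.mean(axis=0)
        total += np.linalg.norm(pts - centroid, axis=1).sum()
    return float(total / len(X))


# --------------------------------------------------------------------------
# Integrated Gradients
# --------------------------------------------------------------------------

def integrated_gradients(f, x: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64) -> np.ndarray:
    """Riemann-sum Integrated Gradients of scalar function ``f``.

    ``IG_i = (x_i - b_i) * (1/steps) * sum_m df/dx_i`` along the straight
    path from ``b`` to ``x``, evaluated at midpoint nodes
    ``b + ((m - 1/2)/steps)(x - b)`` — the midpoint rule integrates the
    gradient of any quadratic model exactly and converges O(1/steps^2)
    otherwise, so completeness ``sum(IG) ~ f(x) - f(b)`` holds tightly.
    ``f`` maps a Tensor to a scalar Tensor.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float64)
    diff = x - b
    acc = np.zeros_like(x)
    for m in range(1, steps + 1):
        point = Tensor(b + ((m - 0.5) / steps) * diff, requires_grad=True)
        out = f(point)
        out.backward()
        acc += point.grad
    return diff * acc / steps


def attribute_example(trained: TrainedModel, dataset, example,
                      steps: int = 64,
                      baseline: np.ndarray | None = None) -> np.ndarray:
    """Per-gene attribution of the causal-branch output for one example,
    taken with respect to the raw profile C (mask included in the path).

    Returns a length-N vector: attributions summed over omic layers.
    """
    model = trained.model
    cell = {p.cell_id: p for p in dataset.profiles}[example.cell_id]
    a = model._drug_index[example.drug_a_id]
    b = model._drug_index[example.drug_b_id]

    def f(C: Tensor) -> Tensor:
        Yc, _ = model.forward_batch(C.reshape(1, *cell.C.shape),
                                    np.array([0]), np.array([a]), np.array([b]))
        return Yc.sum()

    ig = integrated_gradients(f, cell.C, baseline=baseline, steps=steps)
    return ig.sum(axis=0)


def causal_gene_auroc(scores: np.ndarray, causal_genes) -> float:
    """AUROC of planted causal genes under a per-gene score ranking."""
    from sklearn.metrics import roc_auc_score

    y = np.zeros(len(scores), dtype=int)
    y[list(causal_genes)] = 1
    return float(roc_auc_score(y, scores))
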