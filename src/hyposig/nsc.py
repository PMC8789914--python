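"""Nearest-shrunken-centroid (NSC) signature training and classification.

Per gene i and class k the standardized centroid difference is

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

with s_i the pooled within-class standard deviation and s0 the median of
the s_i (the fudge term guarding near-zero variances). Soft-thresholding
by Delta,

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0)

shrinks centroids toward the overall mean; genes with d'_ik = 0 in every
class drop out of the signature. A new sample x* is assigned to the class
minimizing the discriminant

    delta_k(x*) = sum_i (x*_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

over surviving genes, with posterior proportional to exp(-delta_k / 2).
The shrinkage threshold is chosen by stratified cross-validation to
minimize the classification error, ties going to the largest Delta
(fewest genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import AnalysisError, ConfigError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

MAX_MISSING_GENE_FRACTION = 0.5


@dataclass
class NscModel:
    """The signature artifact: centroids, dispersions, shrinkage state."""

    gene_ids: list[str]
    class_names: list[str]
    overall_centroid: np.ndarray        # (genes,)
    class_centroids: np.ndarray         # (genes, classes), unshrunken
    shrunken_centroids: np.ndarray      # (genes, classes)
    s: np.ndarray                       # pooled within-class SD, (genes,)
    s0: float
    m: np.ndarray                       # class size factors, (classes,)
    priors: np.ndarray                  # (classes,)
    delta: float = 0.0
    cv_curve: pd.DataFrame | None = None  # columns delta, error, n_genes

    @property
    def d(self) -> np.ndarray:
        """Unshrunken standardized centroid differences d_ik."""
        denom = self.m[None, :] * (self.s + self.s0)[:, None]
        return (self.class_centroids - self.overall_centroid[:, None]) / denom

    def surviving_genes(self) -> list[str]:
        alive = (self.shrunken_centroids
                 != self.overall_centroid[:, None]).any(axis=1)
        return [g for g, a in zip(self.gene_ids, alive) if a]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        payload = {
            "gene_ids": list(self.gene_ids),
            "class_names": list(self.class_names),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "s0": float(self.s0),
            "m": self.m.tolist(),
            "priors": self.priors.tolist(),
            "delta": float(self.delta),
        }
        if self.cv_curve is not None:
            payload["cv_curve"] = self.cv_curve.to_dict(orient="list")
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "NscModel":
        cv = payload.get("cv_curve")
        return cls(
            gene_ids=list(payload["gene_ids"]),
            class_names=list(payload["class_names"]),
            overall_centroid=np.asarray(payload["overall_centroid"], float),
            class_centroids=np.asarray(payload["class_centroids"], float),
            shrunken_centroids=np.asarray(payload["shrunken_centroids"], float),
            s=np.asarray(payload["s"], float),
            s0=float(payload["s0"]),
            m=np.asarray(payload["m"], float),
            priors=np.asarray(payload["priors"], float),
            delta=float(payload["delta"]),
            cv_curve=pd.DataFrame(cv) if cv is not None else None,
        )


def train_nsc(expr: ExpressionMatrix, labels: pd.Series) -> NscModel:
    """Fit the unshrunken (Delta = 0) model from a labelled cohort."""
    labels = labels.loc[expr.sample_ids]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise AnalysisError("need at least two classes")
    x = expr.values.to_numpy(dtype=float)
    n = x.shape[1]
    n_k = np.array([(labels == k).sum() for k in classes])
    if (n_k < 2).any():
        small = classes[int(np.argmin(n_k))]
        raise AnalysisError(f"class {small!r} has fewer than 2 samples")

    overall = x.mean(axis=1)
    centroids = np.column_stack([
        x[:, (labels == k).to_numpy()].mean(axis=1) for k in classes
    ])
    ss = np.zeros(x.shape[0])
    for j, k in enumerate(classes):
        sub = x[:, (labels == k).to_numpy()]
        ss += ((sub - centroids[:, [j]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    if s0 <= 0:
        s0 = 1e-12  # fully degenerate matrix; keep discriminant finite
    m = np.sqrt(1.0 / n_k - 1.0 / n)
    priors = n_k / n
    return NscModel(
        gene_ids=list(expr.gene_ids), class_names=list(classes),
        overall_centroid=overall, class_centroids=centroids,
        shrunken_centroids=centroids.copy(), s=s, s0=s0, m=m,
        priors=priors, delta=0.0,
    )


def shrink(model: NscModel, delta: float) -> NscModel:
    """Soft-threshold the standardized differences by ``delta``."""
    if delta < 0:
        raise ConfigError("shrinkage threshold must be non-negative")
    d = model.d
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    denom = model.m[None, :] * (model.s + model.s0)[:, None]
    shrunken = model.overall_centroid[:, None] + denom * d_shrunk
    return NscModel(
        gene_ids=model.gene_ids, class_names=model.class_names,
        overall_centroid=model.overall_centroid,
        class_centroids=model.class_centroids,
        shrunken_centroids=shrunken, s=model.s, s0=model.s0, m=model.m,
        priors=model.priors, delta=float(delta), cv_curve=model.cv_curve,
    )


def classify(model: NscModel, expr_new: ExpressionMatrix) -> pd.DataFrame:
    """Assign each sample the class with minimal shrunken-centroid distance.

    Returns a DataFrame indexed by sample with columns ``label`` and one
    posterior column per class. Model genes absent from the cohort are
    dropped from the discriminant symmetrically; classification is
    refused when more than half are missing.
    """
    present = [g for g in model.gene_ids if g in expr_new.gene_ids]
    missing_frac = 1.0 - len(present) / len(model.gene_ids)
    if not present:
        raise AnalysisError("no model genes present in the new cohort")
    if missing_frac > MAX_MISSING_GENE_FRACTION:
        raise AnalysisError(
            f"{missing_frac:.0%} of model genes missing from the cohort "
            f"(limit {MAX_MISSING_GENE_FRACTION:.0%})"
        )
    if missing_frac > 0:
        logger.warning("classifying with %.1f%% of model genes missing",
                       100 * missing_frac)

    gene_pos = {g: i for i, g in enumerate(model.gene_ids)}
    idx = np.array([gene_pos[g] for g in present])
    alive = (model.shrunken_centroids[idx]
             != model.overall_centroid[idx, None]).any(axis=1)
    use = idx[alive] if alive.any() else np.array([], dtype=int)

    x = expr_new.values.loc[present].to_numpy(dtype=float)
    x = x[alive] if alive.any() else np.empty((0, x.shape[1]))
    denom2 = ((model.s + model.s0) ** 2)[use][:, None, None]
    # (genes, samples, classes)
    if use.size:
        diff = x[:, :, None] - model.shrunken_centroids[use][:, None, :]
        dist = (diff ** 2 / denom2).sum(axis=0)
    else:
        dist = np.zeros((expr_new.shape[1], len(model.class_names)))
    delta_k = dist - 2.0 * np.log(model.priors)[None, :]

    label_idx = np.argmin(delta_k, axis=1)
    z = -0.5 * (delta_k - delta_k.min(axis=1, keepdims=True))
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)

    out = pd.DataFrame(post, index=expr_new.sample_ids,
                       columns=[f"posterior_{k}" for k in model.class_names])
    out.insert(0, "label", [model.class_names[i] for i in label_idx])
    return out


def delta_grid(model: NscModel, n_points: int = 30) -> np.ndarray:
    """Linear grid from 0 to the largest |d_ik| (total shrinkage)."""
    return np.linspace(0.0, float(np.abs(model.d).max()), n_points)


def _stratified_folds(labels: pd.Series, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    pos = {s: i for i, s in enumerate(labels.index)}
    for k in labels.unique():
        members = [pos[s] for s in labels.index[labels == k]]
        members = list(rng.permutation(members))
        for i, sample in enumerate(members):
            folds[i % n_folds].append(sample)
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate_threshold(
    expr: ExpressionMatrix, labels: pd.Series, grid: np.ndarray | None = None,
    n_folds: int = 10, seed: int = 0,
) -> tuple[pd.DataFrame, float, NscModel]:
    """Choose the shrinkage threshold minimizing stratified CV error.

    Ties in CV error resolve to the largest threshold (fewest genes);
    the final model is refit on all samples at the chosen threshold.
    Folds too small to contain both classes trigger a fold-count
    reduction with a warning.
    """
    labels = labels.loc[expr.sample_ids]
    full = train_nsc(expr, labels)
    if grid is None:
        grid = delta_grid(full)

    min_class = labels.value_counts().min()
    if min_class < n_folds:
        logger.warning("reducing folds from %d to %d (smallest class)",
                       n_folds, min_class)
        n_folds = int(min_class)
    if n_folds < 2:
        raise AnalysisError("fewer than 2 usable cross-validation folds")

    rng = child_rng(seed, "nsc_cv")
    folds = _stratified_folds(labels, n_folds, rng)
    errors = np.zeros(len(grid))
    n_total = 0
    for held in folds:
        mask = np.ones(len(labels), dtype=bool)
        mask[held] = False
        train_expr = ExpressionMatrix(expr.values.iloc[:, mask],
                                      scale=expr.scale, centred=expr.centred)
        test_expr = ExpressionMatrix(expr.values.iloc[:, held],
                                     scale=expr.scale, centred=expr.centred)
        base = train_nsc(train_expr, labels.iloc[mask])
        truth = labels.iloc[held]
        n_total += len(held)
        for gi, delta in enumerate(grid):
            calls = classify(shrink(base, delta), test_expr)["label"]
            errors[gi] += int((calls != truth).sum())
    error_rate = errors / n_total
    n_genes = [len(shrink(full, d).surviving_genes()) for d in grid]
    curve = pd.DataFrame({"delta": grid, "error": error_rate,
                          "n_genes": n_genes})

    best = error_rate.min()
    chosen = float(grid[np.flatnonzero(error_rate == best)[-1]])
    final = shrink(full, chosen)
    final.cv_curve = curve
    return curve, chosen, final
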