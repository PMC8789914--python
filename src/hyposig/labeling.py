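"""Cohort preprocessing, two-group clustering and hypoxia orientation.

A tumour cohort is log2(x+1)-transformed and per-gene median-centred,
probe-level platforms are collapsed to one probe per gene (drop
decorrelated outlier probes, keep the highest-MAD survivor), samples are
split into two k-means groups on the seed genes, the groups are compared
by moderated-t differential expression, and the cluster whose
up-regulated direction is significantly enriched for the designated
hypoxia gene set (preranked GSEA, positive NES, permutation p below
threshold) receives the hypoxia-high label. If neither cluster qualifies
the orientation is refused rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.cluster import KMeans

from ._rng import child_rng
from .errors import AnalysisError, ConfigError
from .io import ExpressionMatrix, ProbeMap
from .seeds import DEResult, moderated_ttest, bh_fdr

logger = logging.getLogger(__name__)

HYPOXIA_HIGH = "hypoxia-high"
HYPOXIA_LOW = "hypoxia-low"


@dataclass
class GseaResult:
    """Preranked enrichment of one gene set in one ranking."""

    set_name: str
    es: float
    nes: float
    p: float
    n_permutations: int
    leading_edge: list[str] = field(default_factory=list)


@dataclass
class ClusterLabeling:
    """Two-group sample partition, optionally oriented as hypoxia-high/low."""

    assignment: pd.Series            # sample -> "A" | "B"
    inertia: float = float("nan")
    orientation: str | None = None   # cluster name that is hypoxia-high
    status: str = "unoriented"       # unoriented | oriented | refused
    gsea: dict[str, GseaResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        if set(counts.index) != {"A", "B"}:
            raise AnalysisError("labeling must contain exactly clusters A and B, "
                                "both non-empty")

    @property
    def n_per_cluster(self) -> dict[str, int]:
        return self.assignment.value_counts().to_dict()

    def cluster_samples(self, name: str) -> pd.Index:
        return self.assignment.index[self.assignment == name]

    def hypoxia_calls(self) -> pd.Series:
        """Per-sample hypoxia-high/low labels; requires orientation."""
        if self.status != "oriented":
            raise AnalysisError(f"labeling is {self.status}, not oriented")
        return self.assignment.map(
            lambda c: HYPOXIA_HIGH if c == self.orientation else HYPOXIA_LOW
        )


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_cohort(expr: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudo) then per-gene median-centring across the cohort."""
    vals = expr.values.to_numpy(dtype=float)
    if expr.scale != "linear":
        raise AnalysisError("preprocess_cohort expects a linear-scale matrix")
    if (vals < 0).any():
        raise AnalysisError("negative expression values in a linear-scale matrix")
    logv = np.log2(vals + pseudo)
    logv = logv - np.median(logv, axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(logv, index=expr.gene_ids, columns=expr.sample_ids),
        scale="log2", centred=True, platform_tag=expr.platform_tag,
    )


def median_centre(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene median-centring of an already-log2 matrix."""
    if expr.scale != "log2":
        raise AnalysisError("median_centre expects a log2 matrix")
    vals = expr.values.to_numpy(dtype=float)
    vals = vals - np.median(vals, axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=expr.gene_ids, columns=expr.sample_ids),
        scale="log2", centred=True, platform_tag=expr.platform_tag,
    )


# ---------------------------------------------------------------------------
# probe collapse


OUTLIER_PROBE_CORR = 0.25


def collapse_probes(expr: ExpressionMatrix, probe_map: ProbeMap,
                    corr_threshold: float = OUTLIER_PROBE_CORR) -> ExpressionMatrix:
    """One probe per gene: drop outlier probes, keep the max-MAD survivor.

    For genes with >= 3 probes, a probe is an outlier when its Pearson
    correlation with the per-sample median profile of the gene's *other*
    probes falls below ``corr_threshold``. A probe that merely measures
    noise or another transcript is near-uncorrelated (r around 0), while
    concordant probes correlate strongly, so the threshold sits between
    the two populations rather than at zero. Among the survivors the
    probe with the largest median absolute deviation across samples is
    kept; single-probe genes pass through. Ties break on the first probe
    in matrix order.
    """
    if expr.scale != "log2":
        raise AnalysisError("collapse expects a log2 probe matrix")
    genes = probe_map.genes_for(expr.gene_ids)  # raises on unmapped probe
    vals = expr.values
    chosen: dict[str, str] = {}
    n_outliers = 0
    for gene, probes in genes.groupby(genes).groups.items():
        sub = vals.loc[probes]
        if len(probes) == 1:
            chosen[gene] = probes[0]
            continue
        candidates = list(probes)
        if len(probes) >= 3:
            keep = []
            for pid in probes:
                others = sub.drop(index=pid)
                median_profile = others.median(axis=0)
                r = np.corrcoef(sub.loc[pid], median_profile)[0, 1]
                if np.isnan(r) or r >= corr_threshold:
                    keep.append(pid)
                else:
                    n_outliers += 1
                    logger.debug("outlier probe %s for gene %s (r=%.3f)",
                                 pid, gene, r)
            candidates = keep or list(probes)
        mads = median_abs_deviation(vals.loc[candidates], axis=1)
        chosen[gene] = candidates[int(np.argmax(mads))]
    if n_outliers:
        logger.info("removed %d outlier probes", n_outliers)

    order = [chosen[g] for g in sorted(chosen)]
    out = vals.loc[order]
    out.index = pd.Index(sorted(chosen), name="gene_id")
    return ExpressionMatrix(out, scale="log2", centred=expr.centred,
                            platform_tag=expr.platform_tag)


# ---------------------------------------------------------------------------
# clustering


def kmeans_two_group(expr: ExpressionMatrix, seed_genes: list[str],
                     n_starts: int = 50, seed: int = 0) -> ClusterLabeling:
    """k = 2 k-means on samples restricted to the seed-gene rows.

    Best of ``n_starts`` random initializations by within-cluster sum of
    squares. Cluster "A" is the cluster containing the first sample, so
    naming never depends on the k-means internals.
    """
    if not (expr.scale == "log2" and expr.centred):
        raise AnalysisError("clustering expects a log2, median-centred matrix")
    present = [g for g in seed_genes if g in expr.gene_ids]
    absent = len(seed_genes) - len(present)
    if absent:
        logger.warning("%d of %d seed genes absent from cohort", absent,
                       len(seed_genes))
    if len(present) < 2:
        raise AnalysisError("fewer than 2 seed genes present in the matrix")
    x = expr.values.loc[present].to_numpy().T  # samples x genes
    if np.unique(x, axis=0).shape[0] < 2:
        raise AnalysisError("fewer than 2 distinct sample profiles")

    rng = child_rng(seed, "kmeans")
    km = KMeans(n_clusters=2, n_init=n_starts, algorithm="lloyd",
                random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(x)
    first = labels[0]
    names = np.where(labels == first, "A", "B")
    assignment = pd.Series(names, index=expr.sample_ids)
    return ClusterLabeling(assignment=assignment, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# cluster differential expression


def cluster_de(expr: ExpressionMatrix, labeling: ClusterLabeling,
               target: str = "A", fc_threshold: float = 1.5,
               alpha: float = 0.05) -> DEResult:
    """Moderated t of cluster ``target`` vs the other cluster.

    ``up_genes(fc_threshold=...)`` on the result applies the joint
    fold-change > threshold and q < alpha rule.
    """
    assignment = labeling.assignment.loc[expr.sample_ids]
    g1 = (assignment == target).to_numpy()
    g2 = ~g1
    if g1.sum() < 2 or g2.sum() < 2:
        raise AnalysisError("each cluster needs at least 2 samples")
    tab = moderated_ttest(expr.values.to_numpy(), g1, g2)
    tab = tab.set_axis(expr.gene_ids)
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    tab["direction"] = np.where(tab["log2fc"] >= 0, "up", "down")
    return DEResult(tab, alpha=alpha)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_sum_es(metric_sorted: np.ndarray, is_hit: np.ndarray,
                    p: float = 1.0) -> tuple[float, int]:
    """Signed-max running sum over a ranking; returns (ES, argmax position)."""
    weights = np.abs(metric_sorted) ** p
    hit_total = weights[is_hit].sum()
    n_miss = is_hit.size - int(is_hit.sum())
    if hit_total == 0 or n_miss == 0:
        raise AnalysisError("degenerate ranking for enrichment scoring")
    steps = np.where(is_hit, weights / hit_total, -1.0 / n_miss)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_preranked(ranking: pd.Series, gene_set: list[str], n_perm: int = 1000,
                   weight: float = 1.0, seed: int = 0,
                   set_name: str = "set") -> GseaResult:
    """Classical weighted Kolmogorov–Smirnov preranked enrichment.

    Genes are sorted by decreasing metric; hits advance the running sum by
    |metric|^weight (normalized over the set), misses retreat by
    1/(N - set size); ES is the signed maximum deviation. The null
    resamples gene labels; NES divides ES by the mean |null ES| of
    matching sign and p is the one-sided permutation tail with the +1
    correction.
    """
    if ranking.isna().any():
        raise AnalysisError("ranking contains missing values")
    genes_in = [g for g in gene_set if g in ranking.index]
    if not genes_in:
        raise AnalysisError(f"gene set {set_name!r} entirely outside the ranking")

    order = ranking.sort_values(ascending=False, kind="stable")
    metric = order.to_numpy(dtype=float)
    is_hit = order.index.isin(genes_in)
    es, argmax = _running_sum_es(metric, is_hit, weight)

    hit_pos = np.flatnonzero(is_hit)
    if es >= 0:
        leading = list(order.index[hit_pos[hit_pos <= argmax]])
    else:
        leading = list(order.index[hit_pos[hit_pos >= argmax]])

    rng = child_rng(seed, f"gsea:{set_name}")
    n, k = metric.size, len(genes_in)
    null_es = np.empty(n_perm)
    for b in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=k, replace=False)] = True
        null_es[b], _ = _running_sum_es(metric, perm_hit, weight)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same:
        mean_abs = np.abs(null_es[same_sign]).mean()
        nes = es / mean_abs if mean_abs > 0 else 0.0
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    else:
        nes, extreme = 0.0, 0
    p = (1.0 + extreme) / (1.0 + n_same)
    return GseaResult(set_name=set_name, es=es, nes=float(nes), p=float(p),
                      n_permutations=n_perm, leading_edge=leading)


# ---------------------------------------------------------------------------
# orientation


def assign_hypoxia_label(labeling: ClusterLabeling,
                         gsea_by_cluster: dict[str, GseaResult],
                         p_threshold: float = 0.05) -> ClusterLabeling:
    """Orient the clusters: hypoxia-high = significantly positively enriched.

    ``gsea_by_cluster`` maps each cluster name to the enrichment of the
    hypoxia set in that cluster's up-vs-other ranking. Exactly one
    cluster may qualify (NES > 0, p < threshold); two qualifying
    clusters indicate an internal inconsistency; zero means orientation
    is refused.
    """
    if set(gsea_by_cluster) != {"A", "B"}:
        raise ConfigError("gsea_by_cluster must cover clusters A and B")
    qualifying = [c for c, r in gsea_by_cluster.items()
                  if r.nes > 0 and r.p < p_threshold]
    if len(qualifying) == 2:
        raise AnalysisError(
            "both clusters positively enriched for the hypoxia set; "
            "mirror-image rankings cannot both qualify"
        )
    if not qualifying:
        return ClusterLabeling(assignment=labeling.assignment,
                               inertia=labeling.inertia, orientation=None,
                               status="refused", gsea=dict(gsea_by_cluster))
    return ClusterLabeling(assignment=labeling.assignment,
                           inertia=labeling.inertia, orientation=qualifying[0],
                           status="oriented", gsea=dict(gsea_by_cluster))
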