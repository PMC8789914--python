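"""Seed-gene selection from paired hypoxia/normoxia cell-line counts.

Counts are normalized to log2-CPM with trimmed-mean-of-M-values (TMM)
effective library sizes. Differential expression uses a moderated t-test:
per-gene variances are shrunk toward a lowess trend of log-variance
against average log2-CPM, with the prior degrees of freedom estimated by
closed-form moment matching on the log-variance scale. Genes induced
under hypoxia (BH FDR < alpha) in at least ``min_lines`` lines become
seed genes; only up-regulation counts. A pooled variant removes per-line
batch structure by location/scale standardization within each line
before a single pooled test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import AnalysisError, ConfigError
from .io import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

TRIM_LOGRATIO = 0.3  # symmetric trim on M-values
TRIM_ABS = 0.05      # symmetric trim on A-values


@dataclass
class DEResult:
    """Per-gene two-group differential expression summary."""

    table: pd.DataFrame  # columns log2fc, t, p, q, direction; index gene
    alpha: float = 0.05
    n_dropped_constant: int = 0

    def up_genes(self, alpha: float | None = None,
                 fc_threshold: float | None = None) -> pd.Index:
        a = self.alpha if alpha is None else alpha
        tab = self.table
        keep = (tab["q"] < a) & (tab["direction"] == "up")
        if fc_threshold is not None:
            keep &= 2.0 ** tab["log2fc"] > fc_threshold
        return tab.index[keep]


@dataclass
class SeedGeneSet:
    """Genes induced under hypoxia in at least ``min_lines`` cell lines."""

    genes: list[str]
    support: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    alpha: float = 0.05
    min_lines: int = 3


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    lo_m, hi_m = np.quantile(m, [TRIM_LOGRATIO, 1 - TRIM_LOGRATIO])
    lo_a, hi_a = np.quantile(a, [TRIM_ABS, 1 - TRIM_ABS])
    keep2 = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep2.sum() == 0 or w[keep2].sum() == 0:
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_norm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose 75th count percentile (as a
    fraction of library size) is closest to the across-sample mean.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise AnalysisError(f"sample {bad!r} has all-zero counts")
    uq = counts.apply(lambda col: np.quantile(col[col > 0], 0.75), axis=0) / lib
    ref_id = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_id].to_numpy()

    factors = pd.Series(1.0, index=counts.columns)
    for sid in counts.columns:
        if sid == ref_id:
            continue
        factors[sid] = _tmm_factor_pair(counts[sid].to_numpy(), ref,
                                        lib[sid], lib[ref_id])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """log2-CPM with TMM effective library sizes.

    value = log2(count * 1e6 / eff_lib + 0.5); the pseudo-count sits on
    the CPM scale so the transform is exactly invariant to rescaling a
    sample's counts and library size together.
    """
    factors = tmm_norm_factors(counts.counts)
    lib = counts.counts.sum(axis=0).astype(float)
    eff = lib * factors
    cpm = counts.counts.to_numpy(dtype=float) * 1e6 / eff.to_numpy()[None, :]
    values = pd.DataFrame(np.log2(cpm + 0.5), index=counts.counts.index,
                          columns=counts.counts.columns)
    return ExpressionMatrix(values, scale="log2", platform_tag="log2-cpm")


# ---------------------------------------------------------------------------
# moderated t machinery


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float, amean: np.ndarray,
                        frac: float = 0.4) -> tuple[float, np.ndarray]:
    """Estimate prior df and a trended prior variance from observed s^2.

    Moment matching on log(s^2): the residual spread around the lowess
    trend in excess of trigamma(df/2) identifies the prior df.
    """
    ok = s2 > 0
    if ok.sum() < 10:  # too few informative genes to fit a trend
        s0 = np.full_like(s2, max(np.median(s2[ok]) if ok.any() else 1.0, 1e-12))
        return np.inf, s0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    fit = lowess(e, amean[ok], frac=frac, return_sorted=False)
    resid = e - fit
    evar = float(np.var(resid, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        e0 = fit + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        d0 = np.inf
        e0 = fit
    s0 = np.empty_like(s2)
    # genes with zero observed variance inherit the smallest fitted prior
    s0[ok] = np.exp(e0)
    s0[~ok] = np.exp(e0).min() if ok.any() else 1e-12
    return d0, s0


def moderated_ttest(x: np.ndarray, group1: np.ndarray, group2: np.ndarray,
                    df_loss: int = 0,
                    residuals: np.ndarray | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene (rows of x).

    ``group1``/``group2`` are boolean sample masks (group1 minus group2 is
    the reported effect). ``residuals`` optionally supplies the residual
    matrix from a richer linear model; its variance then replaces the
    pooled within-group variance, with ``df_loss`` extra degrees of
    freedom removed from ``n - 2``.
    """
    n1, n2 = int(group1.sum()), int(group2.sum())
    if n1 < 2 or n2 < 2:
        raise AnalysisError("need at least two samples per group")
    x1, x2 = x[:, group1], x[:, group2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    effect = m1 - m2

    if residuals is None:
        ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) \
            + ((x2 - m2[:, None]) ** 2).sum(axis=1)
        df = n1 + n2 - 2 - df_loss
    else:
        ss = (residuals ** 2).sum(axis=1)
        df = n1 + n2 - 2 - df_loss
    if df < 1:
        raise AnalysisError("non-positive residual degrees of freedom")
    s2 = ss / df

    amean = x.mean(axis=1)
    d0, s0 = _fit_variance_prior(s2, df, amean)
    if np.isinf(d0):
        s2_post, df_total = s0, np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"log2fc": effect, "t": t, "p": p})


def _finish_de(tab: pd.DataFrame, index: pd.Index, alpha: float,
               n_dropped: int = 0) -> DEResult:
    tab = tab.set_axis(index)
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    tab["direction"] = np.where(tab["log2fc"] >= 0, "up", "down")
    return DEResult(tab, alpha=alpha, n_dropped_constant=n_dropped)


# ---------------------------------------------------------------------------
# per-line and pooled differential expression


def de_per_line(counts: CountMatrix, line: str, alpha: float = 0.05) -> DEResult:
    """Hypoxia-vs-normoxia moderated t within one cell line."""
    meta = counts.meta
    in_line = meta["line"] == line
    if not in_line.any():
        raise AnalysisError(f"line {line!r} absent from metadata")
    sub = CountMatrix(counts.counts.loc[:, in_line.to_numpy()],
                      meta.loc[in_line])
    cond = sub.meta["condition"]
    hyp = (cond == "hypoxia").to_numpy()
    nor = (cond == "normoxia").to_numpy()
    if hyp.sum() < 2 or nor.sum() < 2:
        raise AnalysisError(
            f"line {line!r} needs >= 2 replicates per condition "
            f"(hypoxia {hyp.sum()}, normoxia {nor.sum()})"
        )
    logcpm = normalize_counts(sub).values.to_numpy()
    tab = moderated_ttest(logcpm, hyp, nor)
    return _finish_de(tab, sub.counts.index, alpha)


def select_seed_genes(de_by_line: dict[str, DEResult], min_lines: int = 3,
                      alpha: float = 0.05) -> SeedGeneSet:
    """Genes up-regulated (q < alpha) in at least ``min_lines`` lines.

    Down-regulation never contributes support, whatever its significance.
    """
    if min_lines > len(de_by_line):
        raise ConfigError(
            f"min_lines={min_lines} exceeds the {len(de_by_line)} lines supplied"
        )
    support = None
    for de in de_by_line.values():
        tab = de.table
        up = ((tab["q"] < alpha) & (tab["direction"] == "up")).astype(int)
        support = up if support is None else support.add(up, fill_value=0)
    support = support.astype(int)
    genes = list(support.index[support >= min_lines])
    return SeedGeneSet(genes=genes, support=support.loc[genes],
                       alpha=alpha, min_lines=min_lines)


def pooled_de_with_batch(counts: CountMatrix, alpha: float = 0.05) -> DEResult:
    """One pooled hypoxia-vs-normoxia test after per-line batch adjustment.

    Within each line, each gene is location-centred, removing the line
    offset; the balanced design leaves the hypoxia contrast intact. The
    pooled moderated t then uses residual df = n - n_lines - 1 to account
    for the per-line centring and the condition effect. Rescaling by
    per-line residual SDs is deliberately avoided: with a handful of
    samples per line those SD estimates are so noisy that dividing by
    them destroys the calibration of the pooled test.
    """
    lines = counts.lines
    if len(lines) < 2:
        raise AnalysisError("batch adjustment needs at least two lines")
    logcpm = normalize_counts(counts).values
    x = logcpm.to_numpy().copy()
    meta = counts.meta
    hyp = (meta["condition"] == "hypoxia").to_numpy()
    nor = ~hyp

    # per-line residual variance around condition means, to identify genes
    # with no within-line variation at all
    resid_var = {}
    for line in lines:
        sel = (meta["line"] == line).to_numpy()
        ss = np.zeros(x.shape[0])
        df_line = 0
        for cond_mask in (hyp & sel, nor & sel):
            if cond_mask.sum() >= 2:
                sub = x[:, cond_mask]
                ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                df_line += cond_mask.sum() - 1
        resid_var[line] = ss / max(df_line, 1)

    pooled_sd = np.sqrt(np.mean(np.column_stack(list(resid_var.values())), axis=1))
    constant = pooled_sd == 0
    if constant.any():
        logger.info("dropping %d genes constant within every line", constant.sum())

    for line in lines:
        sel = (meta["line"] == line).to_numpy()
        x[:, sel] -= x[:, sel].mean(axis=1, keepdims=True)

    keep = ~constant
    resid = x[keep].copy()
    for cond_mask in (hyp, nor):
        resid[:, cond_mask] -= resid[:, cond_mask].mean(axis=1, keepdims=True)
    # remove per-line condition-mean structure from the residuals as well:
    # the centring above already absorbed line offsets, so the remaining
    # df are n - n_lines - 1
    tab = moderated_ttest(x[keep], hyp, nor, df_loss=len(lines) - 1,
                          residuals=resid)
    return _finish_de(tab, logcpm.index[keep], alpha,
                      n_dropped=int(constant.sum()))
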