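"""Independent brute-force oracles used by the unit and acceptance suites.

Each function recomputes a quantity from first principles in the most
literal way available (loops, enumeration, fine grids), sharing no code
path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos in range(n):
        candidates = [p[order[j]] * n / (j + 1) for j in range(rank_pos, n)]
        q[order[rank_pos]] = min(1.0, min(candidates))
    return q


def gsea_es_bruteforce(metric: np.ndarray, is_hit: np.ndarray,
                       weight: float = 1.0) -> float:
    """Recompute the enrichment score position by position."""
    n = metric.size
    hit_norm = sum(abs(metric[i]) ** weight for i in range(n) if is_hit[i])
    n_miss = n - int(is_hit.sum())
    best, running = 0.0, 0.0
    for i in range(n):
        if is_hit[i]:
            running += abs(metric[i]) ** weight / hit_norm
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def nsc_quantities(x: np.ndarray, labels: list[str]):
    """Direct per-formula NSC training quantities for a small instance.

    Returns dict with overall, centroids, s, s0, m, d, priors; class
    order is sorted label order.
    """
    classes = sorted(set(labels))
    labels = np.asarray(labels)
    g, n = x.shape
    overall = np.array([np.mean(x[i]) for i in range(g)])
    cent = np.zeros((g, len(classes)))
    for j, k in enumerate(classes):
        for i in range(g):
            cent[i, j] = np.mean(x[i, labels == k])
    s = np.zeros(g)
    for i in range(g):
        ss = 0.0
        for j, k in enumerate(classes):
            for v in x[i, labels == k]:
                ss += (v - cent[i, j]) ** 2
        s[i] = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    n_k = np.array([(labels == k).sum() for k in classes])
    m = np.sqrt(1.0 / n_k - 1.0 / n)
    d = np.zeros_like(cent)
    for i in range(g):
        for j in range(len(classes)):
            d[i, j] = (cent[i, j] - overall[i]) / (m[j] * (s[i] + s0))
    return {"overall": overall, "centroids": cent, "s": s, "s0": s0,
            "m": m, "d": d, "priors": n_k / n, "classes": classes}


def nsc_classify_bruteforce(x_new: np.ndarray, shrunken: np.ndarray,
                            s: np.ndarray, s0: float,
                            priors: np.ndarray, alive: np.ndarray):
    """Per-sample discriminant computed in explicit loops."""
    n_samples = x_new.shape[1]
    n_classes = shrunken.shape[1]
    labels = np.zeros(n_samples, dtype=int)
    posts = np.zeros((n_samples, n_classes))
    for j in range(n_samples):
        delta = np.zeros(n_classes)
        for k in range(n_classes):
            acc = 0.0
            for i in range(shrunken.shape[0]):
                if alive[i]:
                    acc += (x_new[i, j] - shrunken[i, k]) ** 2 / (s[i] + s0) ** 2
            delta[k] = acc - 2.0 * np.log(priors[k])
        labels[j] = int(np.argmin(delta))
        w = np.exp(-0.5 * (delta - delta.min()))
        posts[j] = w / w.sum()
    return labels, posts


def logrank_tabulation(times, events, group):
    """O, E, V tabulated at each distinct event time; chi-square statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == levels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == levels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e ** 2 / var) if var > 0 else 0.0


def cox_loglik_breslow_free(beta: float, times, events, x):
    """Partial log-likelihood for one covariate, no tied event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for j in np.flatnonzero(events == 1):
        risk = times >= times[j]
        ll += beta * x[j] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_beta_gridsearch(times, events, x, lo=-5.0, hi=5.0):
    """Maximize the partial likelihood on successively refined grids."""
    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        ll = [cox_loglik_breslow_free(b, times, events, x) for b in grid]
        i = int(np.argmax(ll))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 200)]
    return float(grid[i])


def wilcoxon_exact_p(x, y):
    """Two-sided p by full enumeration of group assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    n = len(pooled)
    count = total = 0
    mean_u = nx * len(y) / 2.0
    for combo in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj) \
            + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def fixed_effect_wls(ln_hr: np.ndarray, se: np.ndarray):
    """Weighted least squares intercept-only fit: pooled effect and SE."""
    w = 1.0 / se**2
    xtx = w.sum()
    beta = (w * ln_hr).sum() / xtx
    return beta, np.sqrt(1.0 / xtx)


def kmeans_best_two_partition(x: np.ndarray):
    """Exhaustive minimum within-cluster SS over all 2-partitions.

    x is samples x features; returns (best_assignment, best_ss).
    """
    n = x.shape[0]
    best, best_ss = None, np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or (~mask).all():
            continue
        ss = 0.0
        for m in (mask, ~mask):
            c = x[m].mean(axis=0)
            ss += ((x[m] - c) ** 2).sum()
        if ss < best_ss:
            best, best_ss = mask.copy(), ss
    return best, best_ss
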