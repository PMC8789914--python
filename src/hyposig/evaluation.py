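"""Monte-Carlo evaluation of the pipeline against simulator ground truth.

Each routine regenerates its inputs from seeds, runs the relevant stage
and measures recovery, calibration or prognostic performance. They back
both the validation analyses and the acceptance checks, so problem sizes
are chosen to finish on a single CPU in minutes: 2000-gene cell-line
simulations, cohorts of a few hundred samples, and 20-seed replications.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_rng
from .io import ClinicalTable
from .labeling import gsea_preranked
from .pipeline import run_derive_synthetic
from .seeds import de_per_line, pooled_de_with_batch, select_seed_genes
from .simulate import (CellLineSimConfig, CohortSimConfig,
                       simulate_cell_line_counts, simulate_tumor_cohort)
from .survival import cox_fit, wilcoxon_rank_sum


def seed_gene_recovery(seeds, min_lines: int = 3) -> pd.DataFrame:
    """Recovery/false-call rates of the seed rule at default conditions.

    Recovery = selected true program genes with line support >= min_lines
    over all such genes; false rate = selected genes outside the program
    over all selected.
    """
    rows = []
    for seed in seeds:
        counts, truth = simulate_cell_line_counts(CellLineSimConfig(seed=seed))
        de = {line: de_per_line(counts, line) for line in counts.lines}
        picked = set(select_seed_genes(de, min_lines=min_lines).genes)
        support = truth.support()
        recoverable = set(support.index[support >= min_lines])
        program = set(truth.program_gene_ids)
        rows.append({
            "seed": seed,
            "recovery": len(picked & recoverable) / len(recoverable),
            "false_rate": len(picked - program) / max(len(picked), 1),
            "n_selected": len(picked),
        })
    return pd.DataFrame(rows)


def cv_signature_purity(seeds, n_true: int = 35, n_noise: int = 200,
                        n_samples: int = 250,
                        effect_size: float = 1.5) -> pd.DataFrame:
    """Fraction of CV-surviving signature genes that are true program genes.

    Mirrors a seed list refined on a labelled cohort: the latent class
    labels drive the nearest-shrunken-centroid cross-validation over a
    feature set of informative plus noise genes.
    """
    from .labeling import preprocess_cohort
    from .nsc import cross_validate_threshold

    program = [f"P{i:03d}" for i in range(n_true)]
    rows = []
    for seed in seeds:
        cfg = CohortSimConfig(n_samples=n_samples, program_genes=program,
                              n_background_genes=n_noise,
                              effect_size=effect_size, seed=seed)
        expr, _, truth = simulate_tumor_cohort(cfg)
        proc = preprocess_cohort(expr)
        labels = truth.hypoxia_status.map(
            {True: "hypoxia-high", False: "hypoxia-low"})
        _, delta, model = cross_validate_threshold(proc, labels, seed=seed)
        surviving = model.surviving_genes()
        rows.append({
            "seed": seed,
            "n_surviving": len(surviving),
            "purity": len(set(surviving) & set(program))
            / max(len(surviving), 1),
            "delta": delta,
        })
    return pd.DataFrame(rows)


def cox_coverage(n_reps: int = 100, n: int = 600,
                 true_log_hr: float = float(np.log(2.0)),
                 seed: int = 0) -> pd.DataFrame:
    """Wald-CI coverage of the true group log-hazard ratio."""
    rows = []
    for rep in range(n_reps):
        cfg = CohortSimConfig(n_samples=n, program_genes=["p1"],
                              true_log_hr=true_log_hr,
                              censor_admin_months=1e6,
                              dropout_scale_months=1e7,
                              seed=seed * 100000 + rep)
        _, clin, truth = simulate_tumor_cohort(cfg)
        df = clin.data.copy()
        df["grp"] = truth.hypoxia_status.astype(int)
        res = cox_fit(ClinicalTable(df), ["grp"])
        row = res.table.loc["grp"]
        rows.append({
            "rep": rep, "beta": row["beta"],
            "covered": np.log(row["ci_low"]) <= true_log_hr
            <= np.log(row["ci_high"]),
        })
    return pd.DataFrame(rows)


def null_fdr_per_line(seeds) -> pd.DataFrame:
    """False discovery proportions of per-line DE on program-free data."""
    rows = []
    for seed in seeds:
        cfg = CellLineSimConfig(seed=seed, n_program_genes=0)
        counts, _ = simulate_cell_line_counts(cfg)
        for line in counts.lines:
            de = de_per_line(counts, line)
            n_disc = int((de.table["q"] < 0.05).sum())
            rows.append({"seed": seed, "line": line, "n_discoveries": n_disc,
                         "fdp": 1.0 if n_disc else 0.0})
    return pd.DataFrame(rows)


def null_fdr_pooled(seeds) -> pd.DataFrame:
    """False discovery proportions of pooled batch-adjusted DE, null data."""
    rows = []
    for seed in seeds:
        cfg = CellLineSimConfig(seed=seed, n_program_genes=0)
        counts, _ = simulate_cell_line_counts(cfg)
        de = pooled_de_with_batch(counts)
        n_disc = int((de.table["q"] < 0.05).sum())
        rows.append({"seed": seed, "n_discoveries": n_disc,
                     "fdp": 1.0 if n_disc else 0.0})
    return pd.DataFrame(rows)


def gsea_null_pvalues(n_reps: int = 500, n_genes: int = 400,
                      set_size: int = 25, n_perm: int = 200,
                      seed: int = 0) -> np.ndarray:
    """Permutation p-values for random sets against null rankings."""
    rng = child_rng(seed, "gsea_null_eval")
    pvals = np.empty(n_reps)
    genes = [f"g{i}" for i in range(n_genes)]
    for rep in range(n_reps):
        ranking = pd.Series(rng.normal(0, 1, n_genes), index=genes)
        members = list(rng.choice(genes, size=set_size, replace=False))
        res = gsea_preranked(ranking, members, n_perm=n_perm,
                             seed=int(rng.integers(2**31 - 1)))
        pvals[rep] = res.p
    return pvals


def wilcoxon_null_pvalues(n_reps: int = 500, n: int = 25,
                          seed: int = 0) -> np.ndarray:
    """Rank-sum p-values for same-distribution samples."""
    rng = child_rng(seed, "wilcoxon_null_eval")
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        pvals[rep] = wilcoxon_rank_sum(rng.normal(size=n),
                                       rng.normal(size=n))[1]
    return pvals


def end_to_end_runs(seeds, effect_size: float = 1.5) -> pd.DataFrame:
    """Full derivation per seed: status, test-half HR and log-rank p."""
    rows = []
    for seed in seeds:
        res = run_derive_synthetic(seed=seed, effect_size=effect_size)
        row = {"seed": seed, "status": res.status, "hr": np.nan,
               "logrank_p": np.nan, "n_signature_genes": np.nan}
        if res.status == "ok":
            row.update(hr=res.cox_test.hr("hypoxia"),
                       logrank_p=res.logrank_test_half.p,
                       n_signature_genes=len(res.model.surviving_genes()))
        rows.append(row)
    return pd.DataFrame(rows)
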