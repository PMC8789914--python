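"""Synthetic data with known ground truth for every pipeline stage.

Four generators mirror the study design the pipeline assumes:

* paired hypoxia/normoxia cell-line RNA-seq counts (negative-binomial,
  log-normal baseline means, a hypoxia-induced gene program whose per-gene
  support varies across lines);
* tumour cohorts with a latent hypoxia-high/low status that shifts
  program-gene expression (Gaussian in log2 space) and multiplies the
  event hazard (exponential proportional-hazards times, uniform plus
  administrative censoring, clinical covariates with their own effects);
* probe-level microarray platforms (several probes per gene, offsets,
  noise, occasional decorrelated outlier probes);
* gene-set collections containing one hypoxia set that overlaps the true
  program plus uniform decoy sets.

Every artifact draws from its own RNG stream derived from the config seed
by a stable key (see `_rng`), so equal seeds give bit-identical outputs
and new generators never perturb old ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .errors import ConfigError
from .io import ClinicalTable, CountMatrix, ExpressionMatrix, GeneSetCollection, ProbeMap

LOG2E = np.log2(np.e)


# ---------------------------------------------------------------------------
# configs and ground truth


@dataclass
class CellLineSimConfig:
    """Paired hypoxia/normoxia cell-line count simulation.

    Defaults describe four lines in biological triplicate per condition,
    2000 genes of which 60 form a hypoxia-induced program with per-gene
    log2 fold changes in [1, 3]; per-gene line support is drawn from
    ``line_support_probs`` (keys 1..n_lines) so some program genes clear a
    ">= 3 lines" seed rule and some do not.
    """

    n_genes: int = 2000
    n_lines: int = 4
    n_reps: int = 3
    baseline_log_mean_mu: float = 4.0   # natural-log scale of gene mean counts
    baseline_log_mean_sd: float = 1.3
    dispersion: float = 0.1             # NB: var = mu + dispersion * mu^2
    line_effect_sd: float = 0.5         # per-(gene,line) log-scale baseline offset
    n_program_genes: int = 60
    log2fc_low: float = 1.0
    log2fc_high: float = 3.0
    line_support_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.15, 3: 0.30, 4: 0.40}
    )
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_lines, self.n_reps) <= 0:
            raise ConfigError("n_genes, n_lines and n_reps must be positive")
        if self.n_program_genes < 0 or self.n_program_genes > self.n_genes:
            raise ConfigError("n_program_genes must lie in [0, n_genes]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.line_effect_sd < 0:
            raise ConfigError("line_effect_sd must be non-negative")
        if not 0 < self.library_size_range[0] <= self.library_size_range[1]:
            raise ConfigError("library_size_range must be positive and ordered")
        probs = self.line_support_probs
        if set(probs) - set(range(1, self.n_lines + 1)):
            raise ConfigError("line_support_probs keys must lie in 1..n_lines")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("line_support_probs must sum to 1")


@dataclass
class CohortSimConfig:
    """Tumour cohort with latent hypoxia status, expression shift and hazard.

    Expression is Gaussian in log2 space around per-gene baselines and is
    emitted on the linear scale (2^x - 1, so the standard log2(x+1)
    preprocessing recovers it exactly). Event times are exponential under
    proportional hazards with linear predictor
    ``true_log_hr * 1[hypoxia-high] + covariate effects``; observed time is
    the minimum of the event time, a uniform dropout time and the
    administrative horizon.
    """

    n_samples: int = 502
    prevalence: float = 0.5
    program_genes: list[str] = field(default_factory=list)
    effect_size: float = 1.5            # mean log2 shift of program genes
    noise_sd: float = 1.0
    background_corr: float = 0.1        # within-program shared-factor correlation
    platform_shift: float = 0.0
    platform_scale: float = 1.0
    true_log_hr: float = float(np.log(2.0))
    baseline_hazard: float = 0.01       # events per month
    censor_admin_months: float = 120.0
    dropout_scale_months: float = 240.0  # uniform dropout on [0, scale]
    covariate_log_hrs: dict[str, float] = field(
        default_factory=lambda: {
            "stage": 0.0, "sex": 0.0, "age": 0.0, "smoker": 0.0, "margin": 0.0,
        }
    )
    n_background_genes: int = 0         # extra non-program genes to simulate
    background_genes: list[str] | None = None  # explicit names override count
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie strictly in (0, 1)")
        if not self.program_genes:
            raise ConfigError("program_genes must be non-empty")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censor_admin_months <= 0:
            raise ConfigError("censor_admin_months must be positive")
        if not 0 <= self.background_corr < 1:
            raise ConfigError("background_corr must lie in [0, 1)")
        if self.platform_scale <= 0:
            raise ConfigError("platform_scale must be positive")


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    program_gene_ids: list[str] = field(default_factory=list)
    induced: pd.DataFrame | None = None      # genes x lines boolean
    log2fc: pd.Series | None = None          # per program gene
    hypoxia_status: pd.Series | None = None  # per sample, bool
    true_log_hr: float | None = None

    def support(self) -> pd.Series:
        """Number of lines in which each program gene is induced."""
        if self.induced is None:
            raise ValueError("no per-line induction recorded")
        return self.induced.sum(axis=1)


# ---------------------------------------------------------------------------
# cell-line counts


def simulate_cell_line_counts(cfg: CellLineSimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw NB counts for paired hypoxia/normoxia cultures of several lines."""
    cfg.validate()
    rng = child_rng(cfg.seed, "cell_line_counts")

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    lines = [f"LINE{j + 1}" for j in range(cfg.n_lines)]

    base_mu = np.exp(rng.normal(cfg.baseline_log_mean_mu, cfg.baseline_log_mean_sd,
                                cfg.n_genes))
    # cell lines differ in baseline expression gene by gene; this batch
    # structure cancels within a line but matters for pooled analyses
    line_offsets = np.exp(rng.normal(0.0, cfg.line_effect_sd,
                                     (cfg.n_genes, cfg.n_lines))) \
        if cfg.line_effect_sd > 0 else np.ones((cfg.n_genes, cfg.n_lines))

    program_idx = rng.choice(cfg.n_genes, size=cfg.n_program_genes, replace=False)
    program_idx.sort()
    program_genes = [genes[i] for i in program_idx]
    log2fc = rng.uniform(cfg.log2fc_low, cfg.log2fc_high, cfg.n_program_genes)

    supports = np.array(sorted(cfg.line_support_probs))
    probs = np.array([cfg.line_support_probs[s] for s in supports])
    n_supported = rng.choice(supports, size=cfg.n_program_genes, p=probs)
    induced = np.zeros((cfg.n_program_genes, cfg.n_lines), dtype=bool)
    for g, k in enumerate(n_supported):
        induced[g, rng.choice(cfg.n_lines, size=int(k), replace=False)] = True

    # per-sample gene means: baseline, times 2^log2FC for induced program
    # genes in the hypoxia condition of their supported lines
    sample_ids, meta_rows, columns = [], [], []
    for li, line in enumerate(lines):
        for condition in ("hypoxia", "normoxia"):
            mu = base_mu * line_offsets[:, li]
            if condition == "hypoxia":
                boost = np.ones(cfg.n_genes)
                boost[program_idx[induced[:, li]]] = \
                    2.0 ** log2fc[induced[:, li]]
                mu = mu * boost
            for rep in range(1, cfg.n_reps + 1):
                lib = rng.uniform(*cfg.library_size_range)
                mu_s = mu * (lib / mu.sum())
                if cfg.dispersion > 0:
                    r = 1.0 / cfg.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu_s))
                else:
                    counts = rng.poisson(mu_s)
                columns.append(counts)
                sid = f"{line}_{condition[:3]}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append((line, condition, rep))

    counts = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids,
                        columns=["line", "condition", "replicate"])
    truth = GroundTruth(
        program_gene_ids=program_genes,
        induced=pd.DataFrame(induced, index=program_genes, columns=lines),
        log2fc=pd.Series(log2fc, index=program_genes),
    )
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# tumour cohort


def simulate_tumor_cohort(
    cfg: CohortSimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Draw a tumour cohort: expression, clinical covariates, censored survival."""
    cfg.validate()
    rng = child_rng(cfg.seed, "tumor_cohort")
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    status = rng.uniform(size=n) < cfg.prevalence

    program = list(cfg.program_genes)
    if cfg.background_genes is not None:
        background = [g for g in cfg.background_genes if g not in set(program)]
    else:
        background = [f"BG{i:05d}" for i in range(cfg.n_background_genes)]
    genes = program + background
    g = len(genes)

    baseline = rng.normal(6.0, 1.5, g)
    expr = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, (g, n))

    # shared latent factor induces within-program correlation
    if cfg.background_corr > 0 and program:
        shared = rng.normal(0.0, 1.0, n)
        load = np.sqrt(cfg.background_corr) * cfg.noise_sd
        expr[: len(program)] += load * shared[None, :]

    # per-gene program shift, mean effect_size over genes
    if program:
        shift = cfg.effect_size * rng.uniform(0.5, 1.5, len(program))
        expr[: len(program), status] += shift[:, None]

    expr = cfg.platform_shift + cfg.platform_scale * expr
    linear = np.maximum(np.exp2(expr) - 1.0, 0.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(linear, index=genes, columns=samples),
        scale="linear", platform_tag="synthetic-rnaseq",
    )

    # clinical covariates with their own log-hazard effects
    cov = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    cov["stage"] = (rng.uniform(size=n) < 0.3).astype(int)    # 1 = III&IV
    cov["sex"] = (rng.uniform(size=n) < 0.5).astype(int)      # 1 = male
    cov["age"] = np.round(rng.normal(65.0, 8.0, n), 1)
    cov["smoker"] = (rng.uniform(size=n) < 0.7).astype(int)   # 1 = ever
    cov["margin"] = (rng.uniform(size=n) < 0.12).astype(int)  # 1 = R1&R2
    lp = cfg.true_log_hr * status.astype(float)
    for name, beta in cfg.covariate_log_hrs.items():
        if beta and name in cov:
            x = cov[name].to_numpy(dtype=float)
            if name == "age":
                x = x - x.mean()
            lp = lp + beta * x

    event_t = rng.exponential(1.0 / cfg.baseline_hazard, n) * np.exp(-lp)
    dropout_t = rng.uniform(0.0, cfg.dropout_scale_months, n)
    censor_t = np.minimum(dropout_t, cfg.censor_admin_months)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    clin = cov.copy()
    clin.insert(0, "event", event)
    clin.insert(0, "time", np.round(time, 3))
    clinical = ClinicalTable(clin)

    truth = GroundTruth(
        program_gene_ids=program,
        hypoxia_status=pd.Series(status, index=samples),
        true_log_hr=cfg.true_log_hr,
    )
    return matrix, clinical, truth


# ---------------------------------------------------------------------------
# probe-level platform


def simulate_probe_platform(
    expr: ExpressionMatrix,
    probes_per_gene: tuple[int, int] = (2, 4),
    outlier_rate: float = 0.1,
    probe_offset_sd: float = 0.5,
    probe_noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ProbeMap]:
    """Expand a log2 gene matrix to probe level with occasional outlier probes.

    Each gene becomes k probes (k uniform in ``probes_per_gene``), each the
    gene profile plus a probe-specific offset and noise. With probability
    ``outlier_rate`` one probe of a gene is decorrelated by permuting its
    profile across samples.
    """
    if expr.scale != "log2":
        raise ConfigError("probe platform simulation requires a log2 matrix")
    if not 0.0 <= outlier_rate <= 1.0:
        raise ConfigError("outlier_rate must lie in [0, 1]")
    lo, hi = probes_per_gene
    if not 1 <= lo <= hi:
        raise ConfigError("probes_per_gene must be an ordered positive range")

    rng = child_rng(seed, "probe_platform")
    n = expr.shape[1]
    rows, probe_ids, gene_of = [], [], []
    for gene in expr.gene_ids:
        profile = expr.values.loc[gene].to_numpy(dtype=float)
        k = int(rng.integers(lo, hi + 1))
        outlier_j = -1
        if k > 1 and rng.uniform() < outlier_rate:
            outlier_j = int(rng.integers(k))
        for j in range(k):
            base = profile
            if j == outlier_j:
                base = profile[rng.permutation(n)]
            row = base + rng.normal(0.0, probe_offset_sd) \
                + rng.normal(0.0, probe_noise_sd, n)
            rows.append(row)
            probe_ids.append(f"{gene}_p{j + 1}")
            gene_of.append(gene)

    probe_values = pd.DataFrame(np.vstack(rows), index=probe_ids,
                                columns=expr.sample_ids)
    probe_expr = ExpressionMatrix(probe_values, scale="log2",
                                  centred=expr.centred,
                                  platform_tag="synthetic-array")
    pmap = ProbeMap(pd.Series(gene_of, index=pd.Index(probe_ids, name="probe_id")))
    return probe_expr, pmap


# ---------------------------------------------------------------------------
# gene sets


def make_gene_sets(
    truth: GroundTruth,
    universe: list[str],
    n_decoys: int = 20,
    set_size: int = 50,
    overlap_fraction: float = 0.8,
    seed: int = 0,
) -> GeneSetCollection:
    """One HYPOXIA set overlapping the true program, plus uniform decoys."""
    if set_size > len(universe):
        raise ConfigError("set_size exceeds the gene universe")
    rng = child_rng(seed, "gene_sets")
    universe = list(universe)
    program = [gn for gn in truth.program_gene_ids if gn in universe]

    n_prog = min(len(program), int(round(overlap_fraction * set_size)), set_size)
    members = list(rng.choice(program, size=n_prog, replace=False)) if n_prog else []
    rest = [gn for gn in universe if gn not in set(members)]
    fill = set_size - len(members)
    if fill > 0:
        members += list(rng.choice(rest, size=fill, replace=False))

    sets = {"HYPOXIA": members}
    descriptions = {"HYPOXIA": "synthetic hypoxia program set"}
    for d in range(n_decoys):
        name = f"DECOY_{d + 1:03d}"
        sets[name] = list(rng.choice(universe, size=set_size, replace=False))
        descriptions[name] = "uniform decoy set"
    return GeneSetCollection(sets, descriptions)
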