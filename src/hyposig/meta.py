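"""Fixed-effect inverse-variance meta-analysis of hazard ratios.

Per-study standard errors are back-derived from printed 95% confidence
intervals, se = (ln ci_high - ln ci_low) / (2 * 1.959964); studies are
pooled with weights 1/se^2 under a common-effect assumption. Cochran's Q
and I^2 are reported descriptively but never alter the pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io import StudyEffectTable

Z_95 = 1.959964


@dataclass
class StudyEffect:
    """One study's log hazard ratio with its standard error."""

    label: str
    ln_hr: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise AnalysisError(f"study {self.label!r}: se must be positive")
        if self.n < 1:
            raise AnalysisError(f"study {self.label!r}: n must be >= 1")


@dataclass
class MetaResult:
    """Pooled fixed-effect summary with per-study weights."""

    pooled_ln_hr: float
    pooled_se: float
    pooled_hr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    weights: pd.Series      # normalized to sum to 1, index study label
    total_n: int
    q: float                # Cochran's Q, descriptive only
    i2: float               # I^2 in percent, descriptive only


def se_from_ci(hr: float, ci_low: float, ci_high: float, n: int,
               label: str = "study", level: float = 0.95) -> StudyEffect:
    """Back-derive the log-scale standard error from a printed CI."""
    if not 0 < ci_low <= hr <= ci_high:
        raise AnalysisError(
            f"study {label!r}: need 0 < ci_low <= hr <= ci_high, "
            f"got {hr} [{ci_low}-{ci_high}]"
        )
    z = stats.norm.ppf(0.5 + level / 2.0) if level != 0.95 else Z_95
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * z)
    return StudyEffect(label=label, ln_hr=float(np.log(hr)), se=float(se), n=n)


def effects_from_table(table: StudyEffectTable) -> list[StudyEffect]:
    return [
        se_from_ci(row.hr, row.ci_low, row.ci_high, int(row.n), label=row.study)
        for row in table.data.itertuples()
    ]


def fixed_effect_meta(effects: list[StudyEffect]) -> MetaResult:
    """Generic inverse-variance pooling under a fixed-effect model."""
    if not effects:
        raise AnalysisError("no study effects to pool")
    ln_hr = np.array([e.ln_hr for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled = float(np.sum(w * ln_hr) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    q = float(np.sum(w * (ln_hr - pooled) ** 2))
    df = len(effects) - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 and df > 0 else 0.0
    weights = pd.Series(w / w.sum(), index=[e.label for e in effects])
    return MetaResult(
        pooled_ln_hr=pooled, pooled_se=se, pooled_hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z_95 * se)),
        ci_high=float(np.exp(pooled + Z_95 * se)),
        z=float(z), p=float(p), weights=weights,
        total_n=int(sum(e.n for e in effects)), q=q, i2=i2,
    )


def forest_table(effects: list[StudyEffect], result: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-study rows plus the pooled summary."""
    rows = [
        {
            "study": e.label, "ln_hr": e.ln_hr, "se": e.se,
            "hr": float(np.exp(e.ln_hr)),
            "ci_low": float(np.exp(e.ln_hr - Z_95 * e.se)),
            "ci_high": float(np.exp(e.ln_hr + Z_95 * e.se)),
            "weight_pct": 100.0 * result.weights[e.label], "n": e.n,
        }
        for e in effects
    ]
    rows.append({
        "study": "POOLED", "ln_hr": result.pooled_ln_hr, "se": result.pooled_se,
        "hr": result.pooled_hr, "ci_low": result.ci_low,
        "ci_high": result.ci_high, "weight_pct": 100.0,
        "n": result.total_n,
    })
    return pd.DataFrame(rows)
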