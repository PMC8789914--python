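#!/usr/bin/env python
"""Prognostic evaluation of the hypoxia call on the held-out test half.

Classifies the test half with the trained shrunken-centroid model,
censors follow-up at 5 years (60 months) and evaluates the call by
Kaplan-Meier curves, the log-rank test and Cox models: univariable, and
multivariable adjusted for the clinical covariates passing a p < 0.05
univariable screen (the hypoxia call always enters). Writes the Cox
table and the KM curve points.
"""

from pathlib import Path

import pandas as pd

from hyposig.io import ClinicalTable
from hyposig.labeling import HYPOXIA_HIGH
from hyposig.pipeline import (PipelineParams, default_synthetic_bundle,
                              derive_signature, split_cohort)
from hyposig.labeling import preprocess_cohort
from hyposig.survival import (censor_at, cox_fit, kaplan_meier, logrank,
                              univariable_screen)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    counts, _, cohort, clinical, _, gene_sets = default_synthetic_bundle(SEED)
    res = derive_signature(counts, cohort, clinical, gene_sets, seed=SEED)
    if res.status != "ok":
        print(f"derivation stopped: {res.status}")
        return

    params = PipelineParams()
    processed = preprocess_cohort(cohort)
    _, (test_expr, test_clin) = split_cohort(processed, clinical, "sex",
                                             seed=SEED)
    clin = censor_at(test_clin, params.censor_months)
    df = clin.data.copy()
    df["hypoxia"] = (res.test_calls["label"] == HYPOXIA_HIGH) \
        .astype(int).loc[df.index]
    clin = ClinicalTable(df)

    uni = cox_fit(clin, ["hypoxia"])
    lr = logrank(df["time"], df["event"], df["hypoxia"])
    adjusters = univariable_screen(clin, list(params.covariates), alpha=0.05)
    multi = cox_fit(clin, ["hypoxia", *adjusters])

    uni.table.assign(model="univariable").to_csv(
        RESULTS / "cox_test_univariable.tsv", sep="\t")
    multi.table.assign(model="multivariable").to_csv(
        RESULTS / "cox_test_multivariable.tsv", sep="\t")
    km_rows = []
    for grp in (0, 1):
        sub = df[df["hypoxia"] == grp]
        km = kaplan_meier(sub["time"], sub["event"])
        km_rows.append(pd.DataFrame({"group": grp, "time": km.times,
                                     "survival": km.survival,
                                     "at_risk": km.at_risk}))
    pd.concat(km_rows).to_csv(RESULTS / "km_test.tsv", sep="\t", index=False)

    row = uni.table.loc["hypoxia"]
    print(f"test half: n = {uni.n}, events = {uni.n_events}")
    print(f"hypoxia call (univariable): HR {row['hr']:.2f} "
          f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], p = {row['p']:.4f}")
    print(f"log-rank p = {lr.p:.4f}")
    print(f"adjusters passing the p<0.05 screen: {adjusters or 'none'}")
    mrow = multi.table.loc["hypoxia"]
    print(f"hypoxia call (multivariable): HR {mrow['hr']:.2f} "
          f"[{mrow['ci_low']:.2f}-{mrow['ci_high']:.2f}], p = {mrow['p']:.4f}")


if __name__ == "__main__":
    main()
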