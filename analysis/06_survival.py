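#!/usr/bin/env python
"""Kaplan-Meier / log-rank survival analysis for the top concordant gene:
samples are split at the median expression of the marker gene and the two
groups' survival compared.

Reads results/data/ and results/concordance/, writes KM curves and the
log-rank summary into results/survival/.
"""

from pathlib import Path

import pandas as pd

from cnvconcord import concordance, survival
from cnvconcord.pipeline import _write_logrank

DATA = Path("results/data")
CONC = Path("results/concordance")
OUT = Path("results/survival")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = concordance.read_expression(DATA / "expr.tsv")
    surv = survival.read_survival(DATA / "survival.tsv")
    top = pd.read_csv(CONC / "top_genes.tsv", sep="\t")["symbol"].tolist()
    marker = min(top)

    groups = survival.dichotomize_by_median(expr.loc[marker])
    merged = surv.set_index("sample_id").join(groups, how="inner")
    lr = survival.logrank(merged["time"], merged["event"], merged["group"])
    _write_logrank(lr, marker, OUT / "logrank.tsv")
    km_frames = []
    for grp in (survival.LOW, survival.HIGH):
        sel = merged[merged["group"] == grp]
        km = survival.km_curve(sel["time"], sel["event"])
        km.insert(0, "group", grp)
        km_frames.append(km)
    pd.concat(km_frames, ignore_index=True).to_csv(
        OUT / "km.tsv", sep="\t", index=False, float_format="%.6g"
    )

    print(f"marker gene: {marker} (median expression split, ties to 'low')")
    print(f"log-rank chi2 = {lr.chi2:.3f}, p = {lr.p:.3g}")
    print(f"hazard ratio (low vs high) = {lr.hr:.3f} "
          f"(95% CI {lr.ci95[0]:.3f}-{lr.ci95[1]:.3f})")


if __name__ == "__main__":
    main()
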