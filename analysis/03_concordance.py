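#!/usr/bin/env python
"""Rank frequent-loss genes by concordance between copy-number loss and
down-regulation (diploid-baseline Z < -2 in the same sample).

Reads results/data/ and results/cnv/, writes baselines, the concordance
ranking and the top-gene list into results/concordance/.
"""

from pathlib import Path

import pandas as pd

from cnvconcord import classify, concordance

DATA = Path("results/data")
CNV = Path("results/cnv")
OUT = Path("results/concordance")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = concordance.read_expression(DATA / "expr.tsv")
    calls = classify.read_calls(CNV / "calls.tsv")
    summary = pd.read_csv(CNV / "gene_summary.tsv", sep="\t")
    frequent = sorted(summary.loc[summary["frequent_loss"], "symbol"])

    baselines = concordance.diploid_baseline(expr, calls)
    baselines.to_csv(OUT / "baselines.tsv", sep="\t", index=False,
                     float_format="%.6g")
    records = concordance.concordant_genes(calls, expr, z_threshold=-2.0,
                                           symbols=frequent)
    concordance.records_frame(records).to_csv(
        OUT / "concordance.tsv", sep="\t", index=False
    )
    top = concordance.top_genes(records, min_samples=50)
    pd.DataFrame({"symbol": top}).to_csv(OUT / "top_genes.tsv", sep="\t",
                                         index=False)

    print(f"frequent-loss genes tested: {len(frequent)}")
    print(f"concordant genes (>= 1 sample with CNL and Z < -2): {len(records)}")
    print(f"genes concordant in > 50 samples: {len(top)}")
    for r in records[:5]:
        print(f"  {r.symbol}: {r.n_concordant} concordant samples")


if __name__ == "__main__":
    main()
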