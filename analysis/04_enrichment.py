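#!/usr/bin/env python
"""Gene-set over-representation of the concordant genes, with a
100-permutation specificity analysis against random same-size gene sets.

Reads results/data/ and results/concordance/, writes enrichment and
specificity tables into results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from cnvconcord import enrichment, genomic

DATA = Path("results/data")
CONC = Path("results/concordance")
OUT = Path("results/enrichment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = genomic.read_genes(DATA / "genes.bed")
    universe = {g.symbol for g in genes}
    ann = enrichment.read_gmt(DATA / "sets.gmt").restricted(universe)
    query = pd.read_csv(CONC / "concordance.tsv", sep="\t")["symbol"].tolist()

    results = enrichment.enrich(query, ann, alpha=0.05)
    enrichment.results_frame(results).to_csv(
        OUT / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    hits = enrichment.significant_terms(results, alpha=0.05)
    print(f"query: {len(query)} concordant genes; "
          f"background: {len(ann.background)} genes; "
          f"{len(results)} terms tested")
    print(f"terms enriched at adjusted p < 0.05: {len(hits)}")
    for r in results[:3]:
        print(f"  {r.term}: k={r.k}/{r.K}, p_adj={r.p_adj:.3g}")

    if hits:
        spec = enrichment.permutation_specificity(
            hits, ann, pool=sorted(ann.background),
            m=len(set(query) & ann.background),
            n_permutations=100, alpha=0.05, seed=1,
        )
        enrichment.specificity_frame(spec).to_csv(
            OUT / "specificity.tsv", sep="\t", index=False, float_format="%.6g"
        )
        for s in spec:
            print(f"  specificity {s.term}: re-enriched in {s.perm_count}/100 "
                  f"random queries (empirical p = {s.empirical_p:.3g})")


if __name__ == "__main__":
    main()
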