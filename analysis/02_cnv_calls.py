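#!/usr/bin/env python
"""Intersect CNV segments with gene coordinates, classify loss/gain per
gene and sample under the ploidy-conditional criteria, and apply the
2x frequent-loss filter.

Reads results/data/, writes overlaps, the call table and the per-gene
summary into results/cnv/.
"""

from pathlib import Path

from cnvconcord import classify, concordance, genomic

DATA = Path("results/data")
OUT = Path("results/cnv")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genes = genomic.read_genes(DATA / "genes.bed")
    segments = genomic.read_segments(DATA / "cnv_segments.tsv")
    overlaps = genomic.write_overlaps(
        genomic.intersect(genes, segments), OUT / "overlaps.tsv"
    )
    expr = concordance.read_expression(DATA / "expr.tsv")
    samples = sorted(set(expr.columns) | set(overlaps["sample_id"]))
    calls = classify.build_call_table(
        overlaps, sorted(overlaps["symbol"].unique()), samples
    )
    classify.write_calls(calls, OUT / "calls.tsv")
    summary = classify.summarize(calls, ratio=2.0)
    summary.to_csv(OUT / "gene_summary.tsv", sep="\t", index=False)

    n_cnv = overlaps["symbol"].nunique()
    n_freq = int(summary["frequent_loss"].sum())
    print(f"{len(genes)} genes, {len(segments)} segments, "
          f"{len(overlaps)} gene-segment overlaps")
    print(f"genes with >= 1 CNV: {n_cnv}")
    print(f"frequent-loss genes (n_loss >= 2 x n_gain): {n_freq}")


if __name__ == "__main__":
    main()
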