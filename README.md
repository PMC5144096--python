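# cnvconcord

Concordance analysis between somatic copy-number loss (CNL) and gene
down-regulation, in the style of pan-cancer tumor-suppressor screens: genes
that recurrently lose DNA copies *and* lose expression in the same tumor
samples are candidate drivers of expression change during oncogenesis.

The package is aimed at computational biologists who want the full analysis
chain as tested, reusable code — from raw CNV segment tables to a ranked
gene list, gene-set enrichment, an interaction sub-network and survival
curves — together with a synthetic-data generator that plants known signal
so every stage can be validated end to end without external downloads.

## The analysis

1. **Ploidy-aware CNV classification.** A segment with total copy number
   *c* in a sample with average genome ploidy *p* is a **loss** when
   (*p* ≤ 2.7 and *c* = 0) or (*p* > 2.7 and *c* < *p* − 2.7), and a
   **gain** when *c* ≥ 5 (*p* ≤ 2.7) or *c* ≥ 9 (*p* > 2.7). Segments are
   intersected with gene coordinates (BED semantics, ≥ 1 bp overlap) and
   aggregated to per-(gene, sample) calls.
2. **Frequent-loss filter.** A gene is retained when its loss-sample count
   is at least twice its gain-sample count (and at least one loss exists).
3. **Concordance.** For each gene, expression mean μ and sample SD σ are
   estimated over the samples diploid at that gene; sample *s* is
   concordant when it carries a CNL *and* Z = (x − μ)/σ < −2. Genes are
   ranked by concordant-sample count; genes concordant in more than 50
   samples form the top set.
4. **Enrichment.** Upper-tail hypergeometric over-representation of the
   concordant genes in user-supplied gene sets (GMT), Benjamini–Hochberg
   corrected, plus a 100-permutation specificity analysis against random
   same-size gene sets.
5. **Sub-network.** Klein–Ravi greedy spider-merge approximation of the
   node-weighted Steiner tree connecting the concordant genes in an
   interaction network; degree distribution with a log–log power-law
   exponent fit P(k) ∝ k^(−b), shortest-path histogram, and
   single-community Newman modularity Q = e_S/m − (d_S/2m)² with a
   permutation null over random seed sets.
6. **Survival.** Kaplan–Meier curves, the two-group log-rank test and the
   O/E hazard-ratio estimate HR = (O₁/E₁)/(O₂/E₂) for a median expression
   split on the top gene.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (1000 genes × 300 samples, 50 planted loss genes, 4-SD dosage
effect, a planted annotation term, a planted dense network module, and a
planted hazard ratio of 2):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_cnv_calls.py
python analysis/03_concordance.py
python analysis/04_enrichment.py
python analysis/05_subnetwork.py
python analysis/06_survival.py
```

which prints, among other lines:

```
genes with >= 1 CNV: 50
frequent-loss genes (n_loss >= 2 x n_gain): 50
concordant genes (>= 1 sample with CNL and Z < -2): 50
  G0182: 90 concordant samples
  SET001: k=40/40, p_adj=1.61e-57
sub-network: 62 nodes / 64 edges, 12 linker genes, 1 component(s)
degree power-law exponent b = 1.667
modularity Q = 0.0201; permutation p = 0.009901 (vs 100 random seed sets)
hazard ratio (low vs high) = 1.943 (95% CI 1.508-2.504)
```

Reading: all 50 planted loss genes survive the funnel (CNV → frequent loss
→ concordance), each concordant in ≈ 90 of 300 samples (the 30% planted
loss-carrier fraction); the planted term SET001 is the only enriched set
and never re-enriches in 100 random queries; the extracted sub-network
connects all 50 seeds through 12 linkers with a heavy-tailed degree
distribution; its modularity beats all 100 random seed sets (p = 1/101);
and the planted hazard ratio of 2 is recovered as 1.94.

The same stages are available as one command (`cnvconcord run-all
--outdir OUT --seed 1`) or individually (`cnvconcord simulate|intersect|
classify-cnv|concordance|enrich|subnetwork|survival`).

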