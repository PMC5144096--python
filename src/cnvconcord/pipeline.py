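"""End-to-end orchestration: simulate -> intersect -> classify -> concordance
-> enrichment -> sub-network -> survival.

Each stage reads the previous stage's files from the output directory, so
any stage can be re-run individually; all randomness flows from the single
config seed.  Stage wall-times go to the log only — the written outputs
are deterministic, and re-running an unchanged configuration rewrites
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify, concordance, enrichment, genomic, network, simulate, survival

__all__ = ["PipelineConfig", "RunReport", "run_all"]

log = logging.getLogger("cnvconcord")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the standard constants as defaults.

    When ``do_simulate`` is true the synthetic generator writes every input
    into ``outdir``; otherwise the six input paths must point at existing
    files.
    """

    outdir: str = "results/pipeline"
    do_simulate: bool = True
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    genes_path: str | None = None
    segments_path: str | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    network_path: str | None = None
    survival_path: str | None = None
    ploidy_cut: float = 2.7
    loss_cn: float = 0.0
    gain_cn_diploid: float = 5.0
    gain_cn_polyploid: float = 9.0
    loss_gain_ratio: float = 2.0
    z_threshold: float = -2.0
    alpha: float = 0.05
    permutations: int = 100
    top_gene_min_samples: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(simulate.SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"{path}: unknown sim keys {sorted(bad)}")
            for key in ("expr_mean_range", "expr_sd_range", "ploidy_choices",
                        "term_size_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = simulate.SimConfig(**sim_raw)
        return cfg

    def thresholds(self) -> classify.CnvThresholds:
        return classify.CnvThresholds(
            self.ploidy_cut, self.loss_cn, self.gain_cn_diploid, self.gain_cn_polyploid
        )


@dataclass
class RunReport:
    """Per-stage record counts and the deterministic run summary."""

    counts: dict[str, int] = field(default_factory=dict)
    values: dict[str, float] = field(default_factory=dict)
    config_echo: dict[str, Any] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)  # logged, not written
    seed: int = 0

    def write(self, outdir: Path) -> None:
        rows = [("seed", str(self.seed))]
        rows += [(k, str(v)) for k, v in self.counts.items()]
        rows += [(k, f"{v:.6g}") for k, v in self.values.items()]
        rows += [(f"config.{k}", str(v)) for k, v in sorted(self.config_echo.items())]
        with open(outdir / "report.tsv", "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")
        with open(outdir / "report.txt", "w") as fh:
            fh.write("cnvconcord run summary\n")
            fh.write("=" * 40 + "\n")
            for k, v in rows:
                fh.write(f"{k:32s} {v}\n")


class _Stage:
    """Context manager logging stage start/end and recording wall-time."""

    def __init__(self, report: RunReport, name: str):
        self.report, self.name = report, name

    def __enter__(self):
        log.info("stage=%s level=INFO msg=start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.report.timings_s[self.name] = dt
        if exc_type is not None:
            log.error("stage=%s level=ERROR msg=%s", self.name, exc)
            return False
        log.info("stage=%s level=INFO msg=done wall_s=%.2f", self.name, dt)
        return False


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in dependency order and write all outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    report.config_echo = {
        "loss_gain_ratio": cfg.loss_gain_ratio,
        "z_threshold": cfg.z_threshold,
        "alpha": cfg.alpha,
        "permutations": cfg.permutations,
        "top_gene_min_samples": cfg.top_gene_min_samples,
        "ploidy_cut": cfg.ploidy_cut,
        "do_simulate": cfg.do_simulate,
    }
    rng_enrich, rng_net = (
        np.random.default_rng(c)
        for c in np.random.SeedSequence(cfg.seed).spawn(2)
    )

    if cfg.do_simulate:
        with _Stage(report, "simulate"):
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            sim = simulate.simulate_all(sim_cfg, outdir)
            paths = {k: str(v) for k, v in sim.paths.items()}
            cfg.genes_path = paths["genes"]
            cfg.segments_path = paths["segments"]
            cfg.expression_path = paths["expression"]
            cfg.annotation_path = paths["annotation"]
            cfg.network_path = paths["network"]
            cfg.survival_path = paths["survival"]
    for name in ("genes_path", "segments_path", "expression_path",
                 "annotation_path", "network_path", "survival_path"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name} missing: {p!r}")

    with _Stage(report, "intersect"):
        genes = genomic.read_genes(cfg.genes_path)
        segments = genomic.read_segments(cfg.segments_path)
        pairs = genomic.intersect(genes, segments)
        overlaps = genomic.write_overlaps(pairs, outdir / "overlaps.tsv")
        report.counts["genes_read"] = len(genes)
        report.counts["segments_read"] = len(segments)
        report.counts["genes_with_cnv"] = overlaps["symbol"].nunique()

    with _Stage(report, "classify"):
        expr = concordance.read_expression(cfg.expression_path)
        samples = sorted(set(expr.columns) | set(overlaps["sample_id"]))
        cnv_genes = sorted(overlaps["symbol"].unique())
        calls = classify.build_call_table(
            overlaps, cnv_genes, samples, cfg.thresholds()
        )
        classify.write_calls(calls, outdir / "calls.tsv")
        summary = classify.summarize(calls, ratio=cfg.loss_gain_ratio)
        summary.to_csv(outdir / "gene_summary.tsv", sep="\t", index=False)
        frequent = sorted(summary.loc[summary["frequent_loss"], "symbol"])
        report.counts["frequent_loss_genes"] = len(frequent)

    with _Stage(report, "concordance"):
        baselines = concordance.diploid_baseline(expr, calls)
        baselines.to_csv(
            outdir / "baselines.tsv", sep="\t", index=False, float_format="%.6g"
        )
        records = concordance.concordant_genes(
            calls, expr, z_threshold=cfg.z_threshold, symbols=frequent
        )
        concordance.records_frame(records).to_csv(
            outdir / "concordance.tsv", sep="\t", index=False
        )
        concordant = [r.symbol for r in records]
        top = concordance.top_genes(records, cfg.top_gene_min_samples)
        pd.DataFrame({"symbol": top}).to_csv(
            outdir / "top_genes.tsv", sep="\t", index=False
        )
        report.counts["concordant_genes"] = len(concordant)
        report.counts["top_genes"] = len(top)

    with _Stage(report, "enrich"):
        ann = enrichment.read_gmt(cfg.annotation_path)
        universe = {g.symbol for g in genes}
        ann = ann.restricted(universe)
        results = enrichment.enrich(concordant, ann, alpha=cfg.alpha)
        enrichment.results_frame(results).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        hits = enrichment.significant_terms(results, cfg.alpha)
        report.counts["enriched_terms"] = len(hits)
        if hits and concordant:
            spec = enrichment.permutation_specificity(
                hits,
                ann,
                pool=sorted(universe & ann.background),
                m=len(set(concordant) & ann.background),
                n_permutations=cfg.permutations,
                alpha=cfg.alpha,
                seed=rng_enrich,
            )
            enrichment.specificity_frame(spec).to_csv(
                outdir / "specificity.tsv", sep="\t", index=False, float_format="%.6g"
            )

    with _Stage(report, "subnetwork"):
        net = network.read_network(cfg.network_path)
        if concordant:
            sub = network.klein_ravi(net, concordant)
            network.write_sif(sub, outdir / "subnetwork.sif")
            network.write_graphml(sub, outdir / "subnetwork.graphml")
            network.nodes_frame(sub).to_csv(
                outdir / "nodes.tsv", sep="\t", index=False
            )
            topo = network.topology(sub, net)
            _write_topology(topo, outdir / "topology.tsv")
            null_q, mod_p = network.modularity_permutation(
                net,
                seed_pool=sorted(net.nodes()),
                m=len(sub.terminals_included),
                observed_q=topo.Q,
                n_permutations=cfg.permutations,
                seed=rng_net,
            )
            pd.DataFrame({"null_Q": null_q}).to_csv(
                outdir / "modularity_null.tsv", sep="\t", index=False,
                float_format="%.8g",
            )
            report.counts["subnetwork_nodes"] = len(sub.nodes)
            report.counts["subnetwork_edges"] = len(sub.edges)
            report.counts["subnetwork_linkers"] = len(sub.linkers)
            report.values["degree_exponent_b"] = topo.b
            report.values["modularity_Q"] = topo.Q
            report.values["modularity_perm_p"] = mod_p

    with _Stage(report, "survival"):
        surv = survival.read_survival(cfg.survival_path)
        # deterministic marker choice: lexicographically first top gene
        marker = min(top) if top else (min(concordant) if concordant else None)
        if marker is not None and marker in expr.index:
            groups = survival.dichotomize_by_median(expr.loc[marker])
            merged = surv.set_index("sample_id").join(groups, how="inner")
            lr = survival.logrank(merged["time"], merged["event"], merged["group"])
            _write_logrank(lr, marker, outdir / "logrank.tsv")
            km_frames = []
            for grp in (survival.LOW, survival.HIGH):
                sel = merged[merged["group"] == grp]
                km = survival.km_curve(sel["time"], sel["event"])
                km.insert(0, "group", grp)
                km_frames.append(km)
            pd.concat(km_frames, ignore_index=True).to_csv(
                outdir / "km.tsv", sep="\t", index=False, float_format="%.6g"
            )
            report.values["logrank_chi2"] = lr.chi2
            report.values["logrank_p"] = lr.p
            report.values["hazard_ratio"] = lr.hr
            report.counts["survival_marker_gene_n_samples"] = len(merged)

    report.write(outdir)
    log.info("stage=report level=INFO msg=written outdir=%s", outdir)
    return report


def _write_topology(topo: network.TopologySummary, path: Path) -> None:
    rows = [("b", f"{topo.b:.6g}"), ("Q", f"{topo.Q:.6g}"),
            ("unreachable_pairs", str(topo.unreachable_pairs))]
    rows += [(f"degree_{k}", str(v)) for k, v in topo.degree_hist.items()]
    rows += [(f"path_{k}", str(v)) for k, v in topo.path_hist.items()]
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


def _write_logrank(lr: survival.LogRankResult, marker: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchi2\tp\thr\tci_low\tci_high\to1\te1\to2\te2\n")
        fh.write(
            f"{marker}\t{lr.chi2:.6g}\t{lr.p:.6g}\t{lr.hr:.6g}"
            f"\t{lr.ci95[0]:.6g}\t{lr.ci95[1]:.6g}"
            f"\t{lr.o1:.6g}\t{lr.e1:.6g}\t{lr.o2:.6g}\t{lr.e2:.6g}\n"
        )
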