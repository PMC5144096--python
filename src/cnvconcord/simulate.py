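"""Synthetic pan-cancer inputs with planted, recoverable signal.

Generates every input the concordance pipeline consumes — gene coordinates,
per-sample CNV segment profiles with sample-level average ploidy, an
RSEM-like expression matrix with a planted dosage effect, a GMT annotation
with one enriched term, a scale-free interaction network with a planted
dense module, and a survival table with a planted group hazard ratio —
plus a truth manifest recording exactly which genes, term and module carry
signal, so recovery can be scored.

Conventions mirror COSMIC-style tumor exports: only aberrant segments are
emitted (absence of a segment at a gene means copy-neutral there), each
sample has one genome-wide average ploidy, and loss/gain segments are
constructed to satisfy the ploidy-conditional classification criteria in
:mod:`cnvconcord.classify` exactly.

All randomness flows from one integer seed; per-stage substreams are
spawned deterministically from it, so an identical configuration yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .genomic import GeneRecord, CnvSegment
from .survival import dichotomize_by_median, LOW

__all__ = [
    "SimConfig",
    "TruthManifest",
    "SimOutput",
    "simulate_genome",
    "simulate_cnv_profiles",
    "simulate_expression",
    "simulate_annotation",
    "simulate_network",
    "simulate_survival",
    "simulate_all",
]

_GENE_GAP_BP = 10_000       # spacing between adjacent simulated genes
_SEGMENT_PAD_BP = 500       # segments extend past the gene by this margin
_BASE_HAZARD = 0.1          # event hazard of the 'high' expression group
_PLOIDY_CUT = 2.7           # must match the classifier default


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 1000-gene, 300-sample pan-cancer-style cohort in
    which 5% of genes carry recurrent copy-number losses in 30% of samples
    (gains in 5%), and every loss event depresses expression by four
    baseline standard deviations — a strong dosage effect on the scale of
    recurrent homozygous deletions.
    """

    n_genes: int = 1000
    n_samples: int = 300
    n_chromosomes: int = 22
    gene_length_bp: int = 20_000
    chrom_length_bp: int | None = None  # optional cap; sizing error if exceeded
    frac_loss_genes: float = 0.05
    loss_sample_frac: float = 0.3
    gain_sample_frac: float = 0.05
    concordant_frac: float = 1.0  # fraction of planted loss genes with dosage effect
    dosage_delta: float = 4.0     # expression drop in loss samples, in baseline SDs
    expr_mean_range: tuple[float, float] = (200.0, 1000.0)
    expr_sd_range: tuple[float, float] = (20.0, 60.0)
    ploidy_choices: tuple[float, ...] = (2.0, 3.2)
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_overlap: float = 0.8
    net_attachment: int = 3
    planted_module_size: int = 30
    surv_hr: float = 2.0          # hazard multiplier of the 'low' group
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "n_chromosomes", "gene_length_bp",
                     "n_terms", "net_attachment", "planted_module_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_loss_genes", "loss_sample_frac", "gain_sample_frac",
                     "concordant_frac", "planted_term_overlap", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.expr_sd_range[0] <= 0:
            raise ValueError("expr_sd_range lower bound must be > 0")
        if self.expr_mean_range[0] < 0:
            raise ValueError("expr_mean_range must be non-negative")
        if self.surv_hr <= 0:
            raise ValueError("surv_hr must be positive")
        if any(p <= 0 for p in self.ploidy_choices):
            raise ValueError("ploidy choices must be positive")
        if self.frac_loss_genes > 0 and not (
            self.loss_sample_frac > 2 * self.gain_sample_frac
        ):
            raise ValueError(
                "loss_sample_frac must exceed 2 * gain_sample_frac so the "
                "frequent-loss filter is recoverable by construction"
            )
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class TruthManifest:
    """Ledger of planted signal, for recovery scoring."""

    planted_loss_genes: tuple[str, ...]
    planted_concordant_genes: tuple[str, ...]
    planted_term: str
    planted_module_nodes: tuple[str, ...]
    marker_gene: str  # gene whose expression defines the survival groups
    surv_hr_true: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("planted_loss_genes", "planted_concordant_genes",
                    "planted_module_nodes"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimOutput:
    genes: list[GeneRecord]
    segments: list[CnvSegment]
    expression: pd.DataFrame
    annotation_path: Path | None
    network: nx.Graph
    survival: pd.DataFrame
    truth: TruthManifest
    sample_ids: list[str]
    paths: dict[str, Path]


def _substreams(seed: int, n: int = 8) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_genome(cfg: SimConfig) -> list[GeneRecord]:
    """Lay non-overlapping genes on chromosomes, as evenly as possible.

    Coordinates are 0-based half-open, symbols G0001... unique.  If
    ``chrom_length_bp`` is set and the densest chromosome does not fit,
    a sizing error is raised.
    """
    cfg.validate()
    if cfg.n_genes == 0:
        return []
    symbols = _gene_symbols(cfg.n_genes)
    splits = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    genes: list[GeneRecord] = []
    for ci, idxs in enumerate(splits):
        chrom = f"chr{ci + 1}"
        for local, gi in enumerate(idxs):
            start = _GENE_GAP_BP + local * (cfg.gene_length_bp + _GENE_GAP_BP)
            end = start + cfg.gene_length_bp
            if cfg.chrom_length_bp is not None and end > cfg.chrom_length_bp:
                raise ValueError(
                    f"genes do not fit on {chrom}: need {end} bp, "
                    f"have {cfg.chrom_length_bp}"
                )
            genes.append(GeneRecord(symbols[gi], chrom, start, end))
    return genes


def simulate_cnv_profiles(
    genes: Sequence[GeneRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[CnvSegment], pd.Series, dict[str, set[str]], dict[str, set[str]], list[str]]:
    """Aberrant-segment profiles with per-sample ploidy and planted losses.

    Returns (segments, ploidy per sample, loss-sample sets per planted
    gene, gain-sample sets per planted gene, planted loss gene list).
    Loss segments satisfy the CNL criterion for the carrying sample's
    ploidy (total CN 0 in near-diploid samples, below ploidy - 2.7
    otherwise); gain segments likewise satisfy the CNG criterion.
    Non-planted genes receive no aberrant segments.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    samples = _sample_ids(cfg.n_samples)
    ploidy = pd.Series(
        rng.choice(np.asarray(cfg.ploidy_choices, dtype=float), size=cfg.n_samples),
        index=samples,
    )
    n_loss_genes = int(round(cfg.frac_loss_genes * len(genes)))
    planted = sorted(
        rng.choice([g.symbol for g in genes], size=n_loss_genes, replace=False)
    )
    by_symbol = {g.symbol: g for g in genes}
    n_loss = int(round(cfg.loss_sample_frac * cfg.n_samples))
    n_gain = int(round(cfg.gain_sample_frac * cfg.n_samples))

    segments: list[CnvSegment] = []
    loss_map: dict[str, set[str]] = {}
    gain_map: dict[str, set[str]] = {}
    for sym in planted:
        gene = by_symbol[sym]
        carriers = rng.choice(samples, size=n_loss + n_gain, replace=False)
        loss_samples, gain_samples = set(carriers[:n_loss]), set(carriers[n_loss:])
        loss_map[sym] = loss_samples
        gain_map[sym] = gain_samples
        start = max(0, gene.start - _SEGMENT_PAD_BP)
        end = gene.end + _SEGMENT_PAD_BP
        for sid in sorted(loss_samples):
            p = float(ploidy[sid])
            cn = 0.0 if p <= _PLOIDY_CUT else float(rng.uniform(0.0, p - _PLOIDY_CUT))
            segments.append(CnvSegment(sid, gene.chrom, start, end, cn, p))
        for sid in sorted(gain_samples):
            p = float(ploidy[sid])
            cn = (
                float(rng.integers(5, 9))
                if p <= _PLOIDY_CUT
                else float(rng.integers(9, 13))
            )
            segments.append(CnvSegment(sid, gene.chrom, start, end, cn, p))
    segments.sort(key=lambda s: (s.chrom, s.start, s.sample_id))
    return segments, ploidy, loss_map, gain_map, planted


def simulate_expression(
    genes: Sequence[GeneRecord],
    samples: Sequence[str],
    loss_map: Mapping[str, set[str]],
    concordant: Sequence[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """RSEM-like expression: per-gene Gaussian baseline, truncated at zero.

    For genes in ``concordant``, samples in that gene's loss set have
    their mean shifted down by ``dosage_delta`` baseline SDs — the planted
    coupling between copy-number loss and down-regulation.
    """
    concordant_set = set(concordant)
    mat = np.empty((len(genes), len(samples)))
    col_idx = {s: j for j, s in enumerate(samples)}
    for i, gene in enumerate(genes):
        mu = rng.uniform(*cfg.expr_mean_range)
        sd = rng.uniform(*cfg.expr_sd_range)
        row = rng.normal(mu, sd, size=len(samples))
        if gene.symbol in concordant_set:
            for sid in sorted(loss_map.get(gene.symbol, ())):  # dosage effect
                row[col_idx[sid]] = rng.normal(mu - cfg.dosage_delta * sd, sd)
        mat[i] = np.clip(row, 0.0, None)
    return pd.DataFrame(mat, index=[g.symbol for g in genes], columns=list(samples))


def simulate_annotation(
    genes: Sequence[str],
    concordant: Sequence[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[str]], str]:
    """Random gene sets plus one term enriched for the planted genes.

    The planted term contains at least ``planted_term_overlap`` of the
    planted concordant genes, topped up with random background genes to a
    size within ``term_size_range``.
    """
    lo, hi = cfg.term_size_range
    if hi > len(genes):
        raise ValueError("term_size_range exceeds the background size")
    if cfg.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    width = max(3, len(str(cfg.n_terms)))
    term_ids = [f"SET{i + 1:0{width}d}" for i in range(cfg.n_terms)]
    planted_term = term_ids[0]
    terms: dict[str, list[str]] = {}

    conc = sorted(concordant)
    n_core = int(np.ceil(cfg.planted_term_overlap * len(conc)))
    core = sorted(rng.choice(conc, size=n_core, replace=False)) if n_core else []
    size = int(rng.integers(lo, hi + 1))
    size = max(size, len(core))
    others = sorted(set(genes) - set(core))
    filler = sorted(rng.choice(others, size=size - len(core), replace=False))
    terms[planted_term] = sorted(set(core) | set(filler))

    for tid in term_ids[1:]:
        size = int(rng.integers(lo, hi + 1))
        terms[tid] = sorted(rng.choice(sorted(genes), size=size, replace=False))
    return terms, planted_term


def simulate_network(
    genes: Sequence[str],
    concordant: Sequence[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[nx.Graph, list[str]]:
    """Scale-free (preferential-attachment) network with a planted module.

    The planted module is a subset of the planted concordant genes, wired
    into a connected subgraph with excess internal edges, so its extracted
    sub-network scores a higher single-community modularity than random
    gene sets of the same size.
    """
    n = len(genes)
    if n <= cfg.net_attachment:
        raise ValueError("need more genes than the attachment parameter")
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g0 = nx.barabasi_albert_graph(n, cfg.net_attachment, seed=ba_seed)
    perm = list(rng.permutation(list(genes)))
    g = nx.relabel_nodes(g0, {i: perm[i] for i in range(n)})

    pool = sorted(concordant) if concordant else sorted(genes)
    msize = min(cfg.planted_module_size, len(pool))
    module = sorted(rng.choice(pool, size=msize, replace=False)) if msize else []
    if module:
        chain = list(rng.permutation(module))
        for a, b in zip(chain, chain[1:]):  # spanning path: connected by construction
            g.add_edge(a, b)
        extra = 0
        while extra < msize:  # excess internal density
            a, b = rng.choice(module, size=2, replace=False)
            if not g.has_edge(a, b):
                g.add_edge(a, b)
                extra += 1
    return g, module


def simulate_survival(
    samples: Sequence[str],
    groups: pd.Series,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times with a planted group hazard ratio.

    'high'-group samples have hazard h; 'low'-group samples h * surv_hr.
    Censoring is an independent exponential clock calibrated so the
    expected censored fraction is ``censor_rate``.
    """
    hazards = np.where(
        groups.loc[list(samples)].to_numpy() == LOW,
        _BASE_HAZARD * cfg.surv_hr,
        _BASE_HAZARD,
    )
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        hc = _BASE_HAZARD * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / hc, size=len(samples))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(samples), dtype=int)
    time = np.maximum(np.round(time, 4), 1e-4)
    return pd.DataFrame(
        {"sample_id": list(samples), "time": time, "event": event}
    )


def _write_bed(genes: Sequence[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\n")


def _write_segments(segments: Sequence[CnvSegment], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\ttotal_cn\tavg_ploidy\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}"
                f"\t{s.total_cn:.4f}\t{s.avg_ploidy:.2f}\n"
            )


def _write_gmt(terms: Mapping[str, Sequence[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for tid in terms:
            fh.write("\t".join([tid, "synthetic"] + list(terms[tid])) + "\n")


def _write_network(g: nx.Graph, path: Path) -> None:
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def simulate_all(cfg: SimConfig, outdir: str | Path) -> SimOutput:
    """Generate and write every pipeline input plus the truth manifest.

    Files written: genes.bed, cnv_segments.tsv, expr.tsv, sets.gmt,
    network.tsv, survival.tsv, truth.json.  Identical configurations
    (including the seed) produce byte-identical files.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_cnv, rng_conc, rng_expr, rng_ann, rng_net, rng_surv, *_ = _substreams(cfg.seed)

    genes = simulate_genome(cfg)
    samples = _sample_ids(cfg.n_samples)
    segments, _ploidy, loss_map, _gain_map, planted = simulate_cnv_profiles(
        genes, cfg, rng_cnv
    )
    n_conc = int(round(cfg.concordant_frac * len(planted)))
    concordant = sorted(rng_conc.choice(planted, size=n_conc, replace=False))
    expr = simulate_expression(genes, samples, loss_map, concordant, cfg, rng_expr)
    terms, planted_term = simulate_annotation(
        [g.symbol for g in genes], concordant, cfg, rng_ann
    )
    net, module = simulate_network([g.symbol for g in genes], concordant, cfg, rng_net)

    marker = concordant[0] if concordant else genes[0].symbol
    groups = dichotomize_by_median(expr.loc[marker])
    surv = simulate_survival(samples, groups, cfg, rng_surv)

    truth = TruthManifest(
        planted_loss_genes=tuple(planted),
        planted_concordant_genes=tuple(concordant),
        planted_term=planted_term,
        planted_module_nodes=tuple(module),
        marker_gene=marker,
        surv_hr_true=cfg.surv_hr,
        seed=cfg.seed,
    )

    paths = {
        "genes": outdir / "genes.bed",
        "segments": outdir / "cnv_segments.tsv",
        "expression": outdir / "expr.tsv",
        "annotation": outdir / "sets.gmt",
        "network": outdir / "network.tsv",
        "survival": outdir / "survival.tsv",
        "truth": outdir / "truth.json",
    }
    _write_bed(genes, paths["genes"])
    _write_segments(segments, paths["segments"])
    expr.round(4).to_csv(paths["expression"], sep="\t", float_format="%.4f")
    _write_gmt(terms, paths["annotation"])
    _write_network(net, paths["network"])
    surv.to_csv(paths["survival"], sep="\t", index=False, float_format="%.4f")
    truth.to_json(paths["truth"])
    return SimOutput(
        genes=genes,
        segments=segments,
        expression=expr,
        annotation_path=paths["annotation"],
        network=net,
        survival=surv,
        truth=truth,
        sample_ids=samples,
        paths=paths,
    )
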