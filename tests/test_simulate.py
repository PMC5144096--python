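import json

import networkx as nx
import numpy as np
import pytest
from scipy.stats import ks_2samp

from cnvconcord.classify import GAIN, LOSS, classify_segment
from cnvconcord.simulate import (
    SimConfig,
    TruthManifest,
    simulate_all,
    simulate_cnv_profiles,
    simulate_expression,
    simulate_genome,
    simulate_network,
    simulate_survival,
)

SMALL = SimConfig(
    n_genes=120,
    n_samples=60,
    n_chromosomes=4,
    frac_loss_genes=0.1,
    n_terms=8,
    term_size_range=(5, 15),
    planted_module_size=8,
    seed=11,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_loss_genes=1.5),
            dict(expr_sd_range=(0.0, 1.0)),
            dict(loss_sample_frac=0.1, gain_sample_frac=0.06),  # violates 2x margin
            dict(term_size_range=(10, 5)),
            dict(surv_hr=-1.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestGenome:
    def test_even_layout_no_overlap(self):
        genes = simulate_genome(SimConfig(n_genes=10, n_chromosomes=2))
        assert len(genes) == 10
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        assert {len(v) for v in by_chrom.values()} == {5}
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_zero_genes_empty(self):
        assert simulate_genome(SimConfig(n_genes=0)) == []

    def test_unique_symbols(self):
        genes = simulate_genome(SMALL)
        assert len({g.symbol for g in genes}) == len(genes)

    def test_sizing_error_when_chromosome_too_short(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(SimConfig(n_genes=100, n_chromosomes=1,
                                      chrom_length_bp=50_000))


class TestCnvProfiles:
    def test_emitted_segments_satisfy_classifier_exactly(self, rng):
        genes = simulate_genome(SMALL)
        segments, ploidy, loss_map, gain_map, planted = simulate_cnv_profiles(
            genes, SMALL, rng
        )
        loss_pairs = {(g, s) for g, ss in loss_map.items() for s in ss}
        for seg in segments:
            status = classify_segment(seg.total_cn, seg.avg_ploidy)
            sym = next(g.symbol for g in genes
                       if g.chrom == seg.chrom and g.start - 600 <= seg.start <= g.start)
            if (sym, seg.sample_id) in loss_pairs:
                assert status == LOSS
            else:
                assert status == GAIN

    def test_loss_cn_by_ploidy_regime(self, rng):
        cfg = SimConfig(n_genes=50, n_samples=40, frac_loss_genes=0.2, seed=3)
        genes = simulate_genome(cfg)
        segments, ploidy, loss_map, _, _ = simulate_cnv_profiles(genes, cfg, rng)
        loss_pairs = {(g, s) for g, ss in loss_map.items() for s in ss}
        seen_diploid = seen_polyploid = False
        for seg in segments:
            if seg.avg_ploidy <= 2.7 and seg.total_cn < 5:
                assert seg.total_cn == 0.0
                seen_diploid = True
            elif seg.avg_ploidy > 2.7 and seg.total_cn < 9:
                assert seg.total_cn < seg.avg_ploidy - 2.7  # e.g. < 0.5 at 3.2
                seen_polyploid = True
        assert seen_diploid and seen_polyploid

    def test_no_planted_genes_no_segments(self, rng):
        cfg = SimConfig(n_genes=20, n_samples=10, frac_loss_genes=0.0)
        genes = simulate_genome(cfg)
        segments, *_ = simulate_cnv_profiles(genes, cfg, rng)
        assert segments == []

    def test_nonplanted_genes_untouched(self, rng):
        genes = simulate_genome(SMALL)
        segments, _, loss_map, gain_map, planted = simulate_cnv_profiles(
            genes, SMALL, rng
        )
        planted_set = set(planted)
        for seg in segments:
            covered = [g.symbol for g in genes
                       if g.chrom == seg.chrom and seg.start < g.end and g.start < seg.end]
            assert set(covered) <= planted_set


class TestExpression:
    def test_null_dosage_same_distribution(self):
        """dosage_delta=0: loss and diploid samples are exchangeable."""
        cfg = SimConfig(n_genes=2, n_samples=2000, n_chromosomes=1,
                        frac_loss_genes=0.5, dosage_delta=0.0, seed=5)
        genes = simulate_genome(cfg)
        rng = np.random.default_rng(5)
        loss_map = {genes[0].symbol: set(f"S{i + 1:04d}" for i in range(600))}
        samples = [f"S{i + 1:04d}" for i in range(2000)]
        expr = simulate_expression(genes, samples, loss_map,
                                   [genes[0].symbol], cfg, rng)
        row = expr.iloc[0]
        loss_vals = row[list(loss_map[genes[0].symbol])]
        dip_vals = row[[s for s in samples if s not in loss_map[genes[0].symbol]]]
        assert ks_2samp(loss_vals, dip_vals).pvalue > 0.01

    def test_dosage_shift_depresses_loss_samples(self):
        cfg = SimConfig(n_genes=1, n_samples=500, n_chromosomes=1,
                        frac_loss_genes=1.0, dosage_delta=4.0, seed=6)
        genes = simulate_genome(cfg)
        rng = np.random.default_rng(6)
        loss = set(f"S{i + 1:04d}" for i in range(150))
        samples = [f"S{i + 1:04d}" for i in range(500)]
        expr = simulate_expression(genes, samples, {genes[0].symbol: loss},
                                   [genes[0].symbol], cfg, rng)
        row = expr.iloc[0]
        dip = row[[s for s in samples if s not in loss]]
        z = (row[sorted(loss)] - dip.mean()) / dip.std(ddof=1)
        assert z.mean() < -2  # planted concordance recoverable downstream

    def test_non_negative(self, rng):
        cfg = SimConfig(n_genes=30, n_samples=50, dosage_delta=8.0,
                        frac_loss_genes=0.2, expr_mean_range=(10.0, 50.0),
                        expr_sd_range=(5.0, 20.0))
        genes = simulate_genome(cfg)
        samples = [f"S{i + 1:04d}" for i in range(50)]
        loss = {genes[0].symbol: set(samples[:20])}
        expr = simulate_expression(genes, samples, loss, [genes[0].symbol], cfg, rng)
        assert (expr.values >= 0).all()


class TestNetworkAndAnnotation:
    def test_planted_module_connected_and_graph_one_component(self, rng):
        genes = [f"G{i:04d}" for i in range(300)]
        g, module = simulate_network(genes, genes[:40], SMALL, rng)
        assert nx.is_connected(g)
        assert nx.is_connected(g.subgraph(module))

    @pytest.mark.parametrize("seed", range(10))
    def test_heavy_tail_degree_distribution(self, seed):
        genes = [f"G{i:04d}" for i in range(500)]
        rng = np.random.default_rng(seed)
        g, _ = simulate_network(genes, [], SimConfig(n_genes=500), rng)
        degs = sorted(d for _, d in g.degree())
        assert degs[-1] >= 5 * degs[len(degs) // 2]

    def test_annotation_overlap_guarantee(self, rng):
        from cnvconcord.simulate import simulate_annotation

        genes = [f"G{i:04d}" for i in range(200)]
        conc = genes[:20]
        cfg = SimConfig(n_genes=200, n_terms=5, term_size_range=(20, 30),
                        planted_term_overlap=1.0)
        terms, planted = simulate_annotation(genes, conc, cfg, rng)
        assert set(conc) <= set(terms[planted])
        cfg1 = SimConfig(n_genes=200, n_terms=1, term_size_range=(5, 10))
        terms1, _ = simulate_annotation(genes, conc[:5], cfg1, rng)
        assert len(terms1) == 1


class TestSurvival:
    def test_no_censoring_all_events(self, rng):
        import pandas as pd

        cfg = SimConfig(censor_rate=0.0)
        samples = [f"S{i:03d}" for i in range(50)]
        groups = pd.Series(["low"] * 25 + ["high"] * 25, index=samples)
        surv = simulate_survival(samples, groups, cfg, rng)
        assert (surv["event"] == 1).all()
        assert (surv["time"] > 0).all()

    def test_censor_rate_calibrated(self, rng):
        import pandas as pd

        cfg = SimConfig(censor_rate=0.3, surv_hr=1.0)
        samples = [f"S{i:04d}" for i in range(4000)]
        groups = pd.Series(["high"] * 4000, index=samples)
        surv = simulate_survival(samples, groups, cfg, rng)
        frac_censored = (surv["event"] == 0).mean()
        assert 0.25 < frac_censored < 0.35


class TestReproducibility:
    def test_same_seed_byte_identical_files(self, tmp_path):
        a = simulate_all(SMALL, tmp_path / "a")
        b = simulate_all(SMALL, tmp_path / "b")
        for key in a.paths:
            assert a.paths[key].read_bytes() == b.paths[key].read_bytes(), key

    def test_truth_manifest_round_trip(self, tmp_path):
        out = simulate_all(SMALL, tmp_path / "x")
        loaded = TruthManifest.from_json(out.paths["truth"])
        assert loaded == out.truth
        assert set(loaded.planted_concordant_genes) <= set(loaded.planted_loss_genes)
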