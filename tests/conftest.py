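import numpy as np
import networkx as nx
import pytest

from cnvconcord.genomic import CnvSegment, GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def tiny_genes():
    return [
        GeneRecord("G1", "chr1", 100, 200),
        GeneRecord("G2", "chr1", 300, 400),
        GeneRecord("G3", "chr2", 100, 200),
    ]


@pytest.fixture
def tiny_segments():
    return [
        CnvSegment("s1", "chr1", 150, 250, 0.0, 2.0),
        CnvSegment("s1", "chr1", 200, 300, 5.0, 2.0),   # abuts G1, overlaps nothing
        CnvSegment("s2", "chr2", 50, 150, 0.0, 3.2),
    ]


def random_instance(rng, n_genes=200, n_segments=500, n_chroms=3, span=100_000):
    """Random genes + segments on a small genome, for intersection oracles."""
    genes, segs = [], []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 5000))
        genes.append(GeneRecord(f"G{i:04d}", chrom, start, end))
    for j in range(n_segments):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 20_000))
        segs.append(
            CnvSegment(
                f"S{rng.integers(0, 50):03d}", chrom, start, end,
                float(rng.integers(0, 10)), float(rng.choice([2.0, 3.2])),
            )
        )
    return genes, segs


def brute_force_intersect(genes, segments):
    """Quadratic all-pairs oracle for interval intersection."""
    out = []
    for g in genes:
        for s in segments:
            if g.chrom == s.chrom and max(g.start, s.start) < min(g.end, s.end):
                out.append((g, s))
    out.sort(key=lambda p: (p[0].symbol, p[1].sample_id, p[1].start, p[1].end))
    return out


def random_connected_graph(rng, n_max=9):
    """Small random connected graph for exhaustive Steiner oracles."""
    n = int(rng.integers(4, n_max + 1))
    while True:
        p = float(rng.uniform(0.25, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() >= n - 1:
            return nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
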