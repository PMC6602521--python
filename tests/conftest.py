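import numpy as np
import pytest

from cistromego import DecayConfig, GeneAnnotation, Peak


@pytest.fixture
def tiny_genes():
    """Four genes on two chromosomes, 100 kb apart."""
    return [
        GeneAnnotation("gA", "chr1", 100_000, "+"),
        GeneAnnotation("gB", "chr1", 200_000, "-"),
        GeneAnnotation("gC", "chr2", 100_000, "+"),
        GeneAnnotation("gD", "chr2", 200_000, "-"),
    ]


@pytest.fixture
def decay_1kb():
    return DecayConfig(d0=1000)


def make_peak(chrom, center, width=200, score=None):
    return Peak(chrom, center - width // 2, center + width // 2, score)


def random_gene_peak_fixture(rng, n_genes=50, n_peaks=200, genome=1_000_000,
                             n_chroms=2):
    """Random genes and peaks for oracle-equivalence trials."""
    genes = [
        GeneAnnotation(f"g{i}", f"chr{rng.integers(1, n_chroms + 1)}",
                       int(rng.integers(0, genome)))
        for i in range(n_genes)
    ]
    peaks = [
        make_peak(f"chr{rng.integers(1, n_chroms + 1)}",
                  int(rng.integers(100, genome)))
        for _ in range(n_peaks)
    ]
    return genes, peaks


def brute_force_rp(genes, peaks, config):
    """All-pairs oracle for raw RP: double loop, max over a gene's TSSs."""
    scores = {}
    for g in genes:
        total = 0.0
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            d = abs(p.center - g.tss)
            if d <= config.window:
                total += 2.0 ** (-d / config.d0)
        scores[g.gene_id] = max(scores.get(g.gene_id, 0.0), total)
    return scores
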