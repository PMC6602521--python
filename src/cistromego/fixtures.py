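"""Seeded synthetic datasets with the statistical structure the method
assumes.

The generator builds a toy genome of evenly spaced genes on a few
chromosomes, then plants a set of target genes that carry the signal the
pipeline is meant to recover: ChIP-seq peaks cluster near planted TSSs with
exponentially distributed offsets (and higher significance scores than the
uniform background peaks), and the differential-expression table gives
planted targets small p-values with direction-consistent fold changes while
null genes draw p-values uniformly.  GMT files contain the planted term(s)
plus random null terms whose sizes span both size-filter boundaries.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical spec + seed reproduce byte-identical
files.  What the toy genome deliberately lacks: realistic chromosome
lengths, isoform structure (beyond the optional multi-TSS toggle), GC or
mappability biases, and correlated gene programs — so passing tests
demonstrate the machinery recovers planted structure, not performance on
real cistromes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .io import DGERecord, GeneAnnotation, GeneSet, Peak


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_genes: int = 5000
    n_chromosomes: int = 2
    gene_spacing: int = 100_000  # bp between consecutive TSSs
    planted_term_size: int = 50
    n_planted_terms: int = 1
    n_null_terms: int = 50
    # binding model
    peaks_per_target_lambda: float = 5.0  # Poisson mean of signal peaks per target
    signal_distance_scale: float = 300.0  # exponential scale of peak-to-TSS offsets, bp
    n_background_peaks: int = 10_000
    peak_width: int = 200
    signal_score_offset: float = 10.0  # signal -log10 p = offset + Exp(2)
    # expression model
    de_signal_strength: float = 3.0  # planted -log10 p = strength + Exp(2)
    de_fraction_of_targets: float = 1.0  # fraction of planted targets carrying DE signal
    binding_fraction_of_targets: float = 1.0  # fraction carrying binding signal
    direction: str = "up"  # sign of planted log2fc: up/down/mixed
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def chromosome_length(spec: FixtureSpec) -> int:
    genes_per_chrom = -(-spec.n_genes // spec.n_chromosomes)
    return (genes_per_chrom + 1) * spec.gene_spacing


def make_annotation(spec: FixtureSpec) -> list[GeneAnnotation]:
    """Evenly spaced genes, alternating strand, split across chromosomes."""
    if spec.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    genes = []
    genes_per_chrom = -(-spec.n_genes // spec.n_chromosomes)
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        pos_on_chrom = i % genes_per_chrom
        tss = (pos_on_chrom + 1) * spec.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneAnnotation(f"g{i + 1:0{width}d}", chrom, tss, strand))
    return genes


def planted_targets(spec: FixtureSpec, genes: Sequence[GeneAnnotation]) -> list[list[str]]:
    """Deterministic planted term memberships: consecutive gene blocks, one
    block per planted term."""
    ids = [g.gene_id for g in genes]
    terms = []
    for t in range(spec.n_planted_terms):
        lo = t * spec.planted_term_size
        hi = lo + spec.planted_term_size
        if hi > len(ids):
            raise ValueError("not enough genes for the requested planted terms")
        terms.append(ids[lo:hi])
    return terms


def _target_subset(rng, targets: list[str], fraction: float) -> set[str]:
    if fraction <= 0.0:
        return set()
    if fraction >= 1.0:
        return set(targets)
    k = max(1, int(round(fraction * len(targets))))
    return set(rng.choice(targets, size=k, replace=False))


def make_peaks(
    spec: FixtureSpec,
    genes: Sequence[GeneAnnotation],
    rng: Optional[np.random.Generator] = None,
) -> list[Peak]:
    """Signal peaks clustered at planted TSSs plus uniform background.

    Signal peak centers sit at TSS +/- Exp(signal_distance_scale); their
    scores exceed every background score so significance-ranked subsets are
    signal-first.  Background centers are uniform over each chromosome.
    """
    rng = spec.rng() if rng is None else rng
    gene_by_id = {g.gene_id: g for g in genes}
    all_targets = [g for term in planted_targets(spec, genes) for g in term]
    bound = _target_subset(rng, all_targets, spec.binding_fraction_of_targets)
    chrom_len = chromosome_length(spec)
    half = spec.peak_width // 2

    peaks: list[Peak] = []
    for gid in all_targets:
        if gid not in bound:
            continue
        g = gene_by_id[gid]
        n = rng.poisson(spec.peaks_per_target_lambda)
        for _ in range(n):
            offset = rng.exponential(spec.signal_distance_scale)
            sign = -1 if rng.random() < 0.5 else 1
            center = int(max(half, g.tss + sign * offset))
            score = spec.signal_score_offset + rng.exponential(2.0)
            peaks.append(Peak(g.chrom, center - half, center + half, round(score, 3)))
    chroms = sorted({g.chrom for g in genes})
    for _ in range(spec.n_background_peaks):
        chrom = chroms[rng.integers(len(chroms))]
        center = int(rng.integers(half, chrom_len - half))
        score = 0.5 + rng.uniform(0, spec.signal_score_offset - 1.0)
        peaks.append(Peak(chrom, center - half, center + half, round(score, 3)))
    return peaks


def make_dge(
    spec: FixtureSpec,
    genes: Sequence[GeneAnnotation],
    rng: Optional[np.random.Generator] = None,
) -> list[DGERecord]:
    """Planted targets get -log10 p ~ de_signal_strength + Exp(2) with
    direction-consistent log2fc; null genes draw p ~ Uniform(0,1) and small
    symmetric fold changes.  padj is Benjamini-Hochberg over all genes."""
    rng = spec.rng() if rng is None else rng
    all_targets = [g for term in planted_targets(spec, genes) for g in term]
    de_set = _target_subset(rng, all_targets, spec.de_fraction_of_targets)

    ids, pvals, lfcs = [], [], []
    for g in genes:
        ids.append(g.gene_id)
        if g.gene_id in de_set:
            neglog = spec.de_signal_strength + rng.exponential(2.0)
            p = 10.0 ** (-neglog)
            mag = abs(rng.normal(2.0, 0.5))
            if spec.direction == "up":
                lfc = mag
            elif spec.direction == "down":
                lfc = -mag
            else:
                lfc = mag if rng.random() < 0.5 else -mag
        else:
            p = rng.uniform()
            lfc = rng.normal(0.0, 0.5)
        pvals.append(max(p, 1e-300))
        lfcs.append(lfc)

    # Benjamini-Hochberg adjusted p-values
    p = np.asarray(pvals)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    return [
        DGERecord(i, float(l), float(pv), float(a))
        for i, l, pv, a in zip(ids, lfcs, p, adj)
    ]


def make_gmt(
    spec: FixtureSpec,
    genes: Sequence[GeneAnnotation],
    rng: Optional[np.random.Generator] = None,
) -> list[GeneSet]:
    """Planted terms plus random null terms with sizes log-spaced over
    [5, 2500] so both term-size filter boundaries are exercised."""
    rng = spec.rng() if rng is None else rng
    ids = [g.gene_id for g in genes]
    sets = []
    for t, members in enumerate(planted_targets(spec, genes)):
        sets.append(GeneSet(f"PLANTED{t + 1}", f"planted term {t + 1}", frozenset(members)))
    if spec.n_null_terms:
        sizes = np.unique(
            np.round(np.geomspace(5, 2500, spec.n_null_terms)).astype(int)
        )
        sizes = list(sizes) + [int(rng.integers(10, 200)) for _ in
                               range(spec.n_null_terms - len(sizes))]
        for t, size in enumerate(sorted(sizes)):
            size = min(size, len(ids))
            members = frozenset(rng.choice(ids, size=size, replace=False))
            sets.append(GeneSet(f"NULL{t + 1:03d}", f"null term {t + 1}", members))
    return sets


def write_dataset(spec: FixtureSpec, outdir) -> dict:
    """Generate and write a complete dataset; returns the file paths.

    A single generator drawn from ``spec.seed`` feeds every stage in a fixed
    order, so the whole dataset is reproducible from (spec, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = spec.rng()
    genes = make_annotation(spec)
    peaks = make_peaks(spec, genes, rng)
    dge = make_dge(spec, genes, rng)
    sets = make_gmt(spec, genes, rng)

    paths = {
        "annotation": outdir / "annotation.tsv",
        "peaks": outdir / "peaks.bed",
        "dge": outdir / "dge.tsv",
        "gmt": outdir / "sets.gmt",
    }
    gio.write_annotation(genes, paths["annotation"])
    gio.write_peaks_bed(peaks, paths["peaks"])
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in dge],
            "log2FoldChange": [r.log2fc for r in dge],
            "pvalue": [r.pvalue for r in dge],
            "padj": [r.padj for r in dge],
        }
    ).to_csv(paths["dge"], sep="\t", index=False)
    gio.write_gmt(sets, paths["gmt"])
    return {k: str(v) for k, v in paths.items()}
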