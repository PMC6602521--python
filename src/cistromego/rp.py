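"""Regulatory-potential (RP) scoring of genes from ChIP-seq peaks.

A gene's raw RP is the weighted sum of nearby peak contributions, with
weights decaying exponentially in peak-center-to-TSS distance: ``w(d) =
2**(-d/d0)``, so ``d0`` is the half-weight (decay) distance.  Only peaks
within ``window_multiple * d0`` (default 15*d0, closed interval) of the TSS
contribute.  Raw scores over all annotated genes are min-max scaled to
[0, 1]; the adjusted RP subtracts a per-gene baseline (the median scaled RP
over a panel of reference cistromes) to correct for genes that attract peaks
in most experiments.  Genes are ranked by decreasing adjusted RP.

Strand is ignored: the weight depends only on |center - tss|.  Genes whose
chromosome carries no peaks score 0 and still participate in scaling and
ranking.  Multi-TSS genes take the maximum RP over their isoform TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneAnnotation, Peak
from .ranking import RankedGeneList


@dataclass(frozen=True)
class DecayConfig:
    """Decay distance ``d0`` (bp) and the window multiple defining the peak
    inclusion radius ``window_multiple * d0``."""

    d0: float
    window_multiple: float = 15.0

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.window_multiple <= 0:
            raise ValueError("window_multiple must be positive")

    @property
    def window(self) -> float:
        return self.window_multiple * self.d0


def peak_weight(distance, config: DecayConfig):
    """Exponential-decay weight ``2**(-distance/d0)``; 1 at the TSS, 1/2 at
    ``d0``.  Accepts scalars or arrays; negative distances are an error."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    w = np.exp2(-d / config.d0)
    return float(w) if np.isscalar(distance) else w


class _PeakIndex:
    """Sorted per-chromosome peak centers for window queries."""

    def __init__(self, peaks: Sequence[Peak]):
        self._by_chrom: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[int]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p.center)
        for chrom, centers in by_chrom.items():
            self._by_chrom[chrom] = np.sort(np.asarray(centers, dtype=np.int64))

    def centers_within(self, chrom: str, tss: int, radius: float) -> np.ndarray:
        centers = self._by_chrom.get(chrom)
        if centers is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(centers, tss - radius, side="left")
        hi = np.searchsorted(centers, tss + radius, side="right")
        return centers[lo:hi]


def raw_rp(
    tss_list: Sequence[tuple[str, int]],
    peaks: Sequence[Peak] | _PeakIndex,
    config: DecayConfig,
) -> float:
    """Raw RP of one gene given its (chrom, tss) anchors.

    Per TSS: sum of weights over peaks with |center - tss| <= window, same
    chromosome; the gene takes the maximum over its TSSs.  No peaks in the
    window is a valid 0.
    """
    index = peaks if isinstance(peaks, _PeakIndex) else _PeakIndex(peaks)
    best = 0.0
    for chrom, tss in tss_list:
        centers = index.centers_within(chrom, tss, config.window)
        if centers.size:
            d = np.abs(centers - tss)
            best = max(best, float(np.exp2(-d / config.d0).sum()))
    return best


def raw_rp_all(
    genes: Sequence[GeneAnnotation],
    peaks: Sequence[Peak],
    config: DecayConfig,
) -> pd.Series:
    """Raw RP for every annotated gene (index: gene_id, sorted)."""
    index = _PeakIndex(peaks)
    scores: dict[str, float] = {}
    for g in genes:
        centers = index.centers_within(g.chrom, g.tss, config.window)
        rp = float(np.exp2(-np.abs(centers - g.tss) / config.d0).sum()) if centers.size else 0.0
        prev = scores.get(g.gene_id)
        scores[g.gene_id] = rp if prev is None else max(prev, rp)
    s = pd.Series(scores, dtype=float).sort_index()
    s.index.name = "gene_id"
    return s


def scale_rp(raw: pd.Series) -> pd.Series:
    """Min-max scale raw scores to [0, 1]; all-equal input (including a
    single gene) scales to all zeros."""
    if len(raw) == 0:
        raise ValueError("no genes to scale")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return pd.Series(np.zeros(len(raw)), index=raw.index)
    return (raw - lo) / (hi - lo)


def adjust_rp(scaled: pd.Series, baseline: Optional[Mapping[str, float]] = None) -> pd.Series:
    """Adjusted RP = scaled RP - baseline RP.

    Genes absent from the baseline table get baseline 0; with no table the
    adjusted score equals the scaled score.
    """
    if baseline is None:
        return scaled.copy()
    base = scaled.index.map(lambda g: float(baseline.get(g, 0.0)))
    n_missing = sum(1 for g in scaled.index if g not in baseline)
    if n_missing:
        import logging

        logging.getLogger("cistromego").info(
            "baseline: %d genes missing from table, baseline 0 assumed", n_missing
        )
    return scaled - pd.Series(base, index=scaled.index)


def baseline_series(scaled: pd.Series, baseline: Optional[Mapping[str, float]]) -> pd.Series:
    """Per-gene baseline aligned to the scaled index (0 where absent)."""
    if baseline is None:
        return pd.Series(0.0, index=scaled.index)
    return pd.Series(
        [float(baseline.get(g, 0.0)) for g in scaled.index], index=scaled.index
    )


def compute_baseline(
    peak_sets: Sequence[Sequence[Peak]],
    genes: Sequence[GeneAnnotation],
    config: DecayConfig,
) -> dict:
    """Baseline RP per gene: the median of its scaled RP scores over a panel
    of cistromes.  A gene missing from (i.e. unscored in) a dataset
    contributes 0 for that dataset."""
    if not peak_sets:
        raise ValueError("compute_baseline needs at least one peak dataset")
    scaled_cols = []
    for peaks in peak_sets:
        scaled_cols.append(scale_rp(raw_rp_all(genes, peaks, config)))
    mat = pd.concat(scaled_cols, axis=1).fillna(0.0)
    return mat.median(axis=1).to_dict()


def rank_by_adjusted_rp(adjusted: pd.Series) -> RankedGeneList:
    """Rank genes by decreasing adjusted RP; tied scores get mid-ranks, and
    the output list order breaks ties lexicographically by gene_id."""
    ranks = rankdata(-adjusted.values, method="average")
    order = np.lexsort((adjusted.index.values.astype(str), -adjusted.values))
    return RankedGeneList(
        gene_ids=list(adjusted.index[order]),
        scores=list(adjusted.values[order]),
        ranks=pd.Series(ranks, index=adjusted.index),
        higher_is_better=True,
    )


def rp_table(
    raw: pd.Series,
    scaled: pd.Series,
    baseline: pd.Series,
    adjusted: pd.Series,
    ranking: RankedGeneList,
) -> pd.DataFrame:
    """Assemble the per-gene RP output table (rp_ranks.tsv schema)."""
    df = pd.DataFrame(
        {
            "gene_id": raw.index,
            "rp_raw": raw.values,
            "rp_scaled": scaled.values,
            "baseline": baseline.values,
            "rp_adjusted": adjusted.values,
            "rank_rp": ranking.ranks.loc[raw.index].values,
        }
    )
    return df.sort_values(["rank_rp", "gene_id"], kind="stable").reset_index(drop=True)
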