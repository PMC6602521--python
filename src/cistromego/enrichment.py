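"""Threshold-free gene-set enrichment on a gene ranking.

Term pre-processing: every gene set is intersected with the ranking's gene
universe; sets retaining fewer than 10 or more than 2000 universe members
are excluded (too small for reliable analysis / too general to be
informative).  Highly redundant terms (Jaccard index > 0.85) are collapsed,
keeping the larger set.  Each surviving term is translated into a 0/1
indicator over the ranking and tested with the exact minimum-hypergeometric
test; Benjamini-Hochberg FDR is applied across all terms of a collection,
and terms with FDR < 0.2 form the reported table (the full table is always
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSet
from .mhg import mhg_test
from .ranking import RankedGeneList

logger = logging.getLogger("cistromego")

MIN_TERM_SIZE = 10
MAX_TERM_SIZE = 2000
JACCARD_CUTOFF = 0.85
DEFAULT_FDR_CUTOFF = 0.2


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    N: int  # universe size
    B: int  # term size within the universe
    mhg_stat: float
    n_star: int  # optimal cutoff (smallest attaining the minimum)
    b_at_cutoff: int
    pvalue: float
    fdr: float
    enrichment_score: float  # (b/n*)/(B/N), fold enrichment at the cutoff
    member_ranks: list  # (gene_id, rank position) for term members, by rank


def filter_term_sets(sets: Sequence[GeneSet], universe: Iterable[str]) -> list[GeneSet]:
    """Intersect each set with the universe; keep sets with 10..2000
    surviving members (both bounds inclusive)."""
    uni = set(universe)
    kept = []
    for s in sets:
        members = frozenset(s.members & uni)
        if MIN_TERM_SIZE <= len(members) <= MAX_TERM_SIZE:
            kept.append(GeneSet(s.set_id, s.name, members))
    if not kept:
        logger.warning("no gene sets survive the size filter")
    return kept


def jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def dedup_by_jaccard(sets: Sequence[GeneSet], cutoff: float = JACCARD_CUTOFF) -> list[GeneSet]:
    """Greedy redundancy filter: visit sets by decreasing (post-intersection)
    size, ties by set_id; drop a set whose Jaccard index with any
    already-kept set exceeds the cutoff, so the larger of a redundant pair
    survives."""
    ordered = sorted(sets, key=lambda s: (-len(s.members), s.set_id))
    kept: list[GeneSet] = []
    for s in ordered:
        if all(jaccard(s.members, k.members) <= cutoff for k in kept):
            kept.append(s)
    # restore input order among survivors so downstream output is stable
    kept_ids = {s.set_id for s in kept}
    return [s for s in sets if s.set_id in kept_ids]


def run_enrichment(
    ranking: RankedGeneList,
    sets: Sequence[GeneSet],
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> list[EnrichmentResult]:
    """mHG-test every gene set against the ranking; BH-adjust across sets.

    The returned list is sorted by ascending p-value (ties by set_id) and
    covers every tested set; restrict to ``r.fdr < fdr_cutoff`` for the
    reported table.  Sets are assumed pre-filtered and deduplicated.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    if not sets:
        logger.warning("run_enrichment called with no gene sets")
        return []
    N = len(ranking)
    pos = {g: i for i, g in enumerate(ranking.gene_ids)}

    results = []
    pvals = []
    for s in sets:
        ind = np.zeros(N, dtype=np.int64)
        member_pos = sorted(pos[g] for g in s.members if g in pos)
        ind[member_pos] = 1
        B = int(ind.sum())
        stat, n_star, b_at, p = mhg_test(ind)
        es = (b_at / n_star) / (B / N) if B else 0.0
        member_ranks = [(ranking.gene_ids[i], i + 1) for i in member_pos]
        results.append(
            EnrichmentResult(s.set_id, s.name, N, B, stat, n_star, b_at, p,
                             np.nan, es, member_ranks)
        )
        pvals.append(p)

    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form of enrichment results (enrichment_<collection>.tsv
    schema)."""
    rows = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "N": r.N,
            "B": r.B,
            "n_star": r.n_star,
            "b": r.b_at_cutoff,
            "enrichment_score": r.enrichment_score,
            "pvalue": r.pvalue,
            "fdr": r.fdr,
            "genes": ";".join(f"{g}({k})" for g, k in r.member_ranks),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["set_id", "name", "N", "B", "n_star", "b", "enrichment_score",
                 "pvalue", "fdr", "genes"],
    )
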