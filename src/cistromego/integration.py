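"""Integration of binding and differential-expression evidence.

The expression rank R^DE orders genes by ascending differential-expression
p-value, after an optional direction filter (up: log2fc > 0, down:
log2fc < 0).  In ensemble mode the binding rank R^RP and R^DE are combined
by rank product R^RP * R^DE over the intersection of the two gene
universes, both ranks being recomputed within the intersection so the
product compares like with like; genes at the top of the product ordering
carry joint evidence of binding and expression response and are the most
likely direct targets.

ROC and precision-recall diagnostics relate adjusted RP scores (the
predictor) to differential-expression-defined labels (padj below a cutoff,
direction-consistent; falling back to the raw p-value when no adjusted
p-value is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import DGERecord
from .ranking import RankedGeneList

logger = logging.getLogger("cistromego")

DIRECTIONS = ("up", "down", "all")


@dataclass
class CurvePoints:
    """Ordered curve points and the trapezoid area under them."""

    x: np.ndarray
    y: np.ndarray
    auc: float


def _direction_mask(records: Sequence[DGERecord], direction: str) -> list[bool]:
    if direction == "up":
        return [r.log2fc > 0 for r in records]
    if direction == "down":
        return [r.log2fc < 0 for r in records]
    if direction == "all":
        return [True] * len(records)
    raise ValueError(f"unknown direction {direction!r}")


def rank_by_de(records: Sequence[DGERecord], direction: str = "all") -> RankedGeneList:
    """Rank genes by ascending DE p-value after the direction filter; tied
    p-values get mid-ranks; list order breaks ties by gene_id."""
    mask = _direction_mask(records, direction)
    kept = [r for r, m in zip(records, mask) if m]
    if not kept:
        raise ValueError(f"no genes left after direction={direction!r} filter")
    pv = np.array([r.pvalue for r in kept])
    ids = np.array([r.gene_id for r in kept])
    ranks = rankdata(pv, method="average")
    order = np.lexsort((ids, pv))
    return RankedGeneList(
        gene_ids=list(ids[order]),
        scores=list(pv[order]),
        ranks=pd.Series(ranks, index=ids),
        higher_is_better=False,
    )


def rank_product(rp_ranks: RankedGeneList, de_ranks: RankedGeneList) -> pd.DataFrame:
    """Combine two rankings by rank product over their gene intersection.

    Both ranks are recomputed within the intersection (from the original
    ordering scores, preserving tie structure) before multiplication.
    Returns a frame with columns gene_id, rank_rp, rank_de, rank_product,
    final_rank, ordered by final_rank; final ranks are integer positions
    after sorting by (rank_product, gene_id).
    """
    if len(rp_ranks) == 0 or len(de_ranks) == 0:
        raise ValueError("both rankings must be non-empty")
    rp_scores = pd.Series(rp_ranks.scores, index=rp_ranks.gene_ids)
    de_scores = pd.Series(de_ranks.scores, index=de_ranks.gene_ids)
    common = rp_scores.index.intersection(de_scores.index)
    if len(common) == 0:
        raise ValueError("the two rankings share no genes")
    n_drop_rp = len(rp_scores) - len(common)
    n_drop_de = len(de_scores) - len(common)
    if n_drop_rp or n_drop_de:
        logger.info(
            "rank_product: dropped %d binding-only and %d expression-only genes",
            n_drop_rp, n_drop_de,
        )
    common = sorted(common)
    rp_sub = rp_scores.loc[common].astype(float)
    de_sub = de_scores.loc[common].astype(float)
    r_rp = rankdata(-rp_sub.values if rp_ranks.higher_is_better else rp_sub.values,
                    method="average")
    r_de = rankdata(-de_sub.values if de_ranks.higher_is_better else de_sub.values,
                    method="average")
    product = r_rp * r_de
    df = pd.DataFrame(
        {"gene_id": common, "rank_rp": r_rp, "rank_de": r_de, "rank_product": product}
    )
    df = df.sort_values(["rank_product", "gene_id"], kind="stable").reset_index(drop=True)
    df["final_rank"] = np.arange(1, len(df) + 1)
    return df


def ensemble_ranking(table: pd.DataFrame) -> RankedGeneList:
    """Ranked gene list ordered by ascending rank product (smaller = more
    likely direct target)."""
    ranks = pd.Series(
        rankdata(table["rank_product"].values, method="average").astype(float),
        index=table["gene_id"].values,
    )
    return RankedGeneList(
        gene_ids=list(table["gene_id"]),
        scores=list(table["rank_product"]),
        ranks=ranks,
        higher_is_better=False,
    )


def de_labels(
    records: Sequence[DGERecord],
    cutoff: float = 0.05,
    direction: str = "all",
    use: str = "auto",
) -> dict:
    """Differential-expression labels per gene: True = differentially
    expressed (significant and direction-consistent).

    ``use`` selects the significance column: "padj", "pvalue", or "auto"
    (padj when present for a record, else pvalue).
    """
    labels = {}
    mask = _direction_mask(records, direction)
    for r, direction_ok in zip(records, mask):
        if use == "padj" or (use == "auto" and r.padj is not None):
            sig = (r.padj if r.padj is not None else 1.0) < cutoff
        else:
            sig = r.pvalue < cutoff
        labels[r.gene_id] = bool(sig and direction_ok)
    return labels


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> CurvePoints:
    """ROC by sweeping the score threshold from high to low; tied scores are
    grouped into a single step.  Area by the trapezoid rule."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order].astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep only the last index of each tied-score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return CurvePoints(fpr, tpr, auc)


def pr_curve_points(scores: np.ndarray, labels: np.ndarray) -> CurvePoints:
    """Precision-recall by threshold sweep.  The recall-0 anchor takes the
    precision of the single highest-scoring prediction."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order].astype(bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR needs at least one positive label")
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    distinct = np.r_[s[1:] != s[:-1], True]
    precision = tp[distinct] / k[distinct]
    recall = tp[distinct] / n_pos
    p0 = 1.0 if y[0] else 0.0  # precision of the top prediction
    recall = np.r_[0.0, recall]
    precision = np.r_[p0, precision]
    auc = float(np.trapezoid(precision, recall))
    return CurvePoints(recall, precision, auc)


def binding_expression_curves(
    adjusted_rp: Mapping[str, float],
    dge: Sequence[DGERecord],
    label_cutoff: float = 0.05,
    direction: str = "all",
    label_on: str = "auto",
):
    """ROC and PR of adjusted RP against DE-defined labels.

    The evaluation universe is the intersection of scored and measured
    genes.  Positives are genes passing the DE label rule; the remainder of
    the universe are negatives.  Returns ``(roc, pr)`` as
    :class:`CurvePoints`.
    """
    labels_all = de_labels(dge, label_cutoff, direction, label_on)
    genes = sorted(set(adjusted_rp) & set(labels_all))
    if not genes:
        raise ValueError("no genes shared between RP scores and DGE table")
    scores = np.array([adjusted_rp[g] for g in genes], dtype=float)
    labels = np.array([labels_all[g] for g in genes], dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("DE labels are all-positive or all-negative; curves undefined")
    return roc_curve_points(scores, labels), pr_curve_points(scores, labels)
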