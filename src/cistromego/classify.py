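"""Promoter- vs enhancer-dominant classification of a cistrome.

Some TFs (E2F1-like) bind mostly within 1 kb of transcription start sites;
others (AR/ESR1-like) bind mostly distal enhancers.  The classifier computes
the fraction of the most significant peaks (top 2000, 5000, 10000 by
-log10 p-value, each only when that many peaks exist, plus all peaks) whose
center lies within 1 kb of the nearest TSS.  If any fraction exceeds the
threshold (default 20%) the TF is promoter-dominant and the default decay
distance is 1 kb; otherwise enhancer-dominant with 10 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GeneAnnotation, Peak

SUBSET_SIZES = (2000, 5000, 10000)
PROMOTER_D0 = 1000.0
ENHANCER_D0 = 10000.0


@dataclass
class ClassificationReport:
    fractions: dict  # subset label ("2000", ..., "all") -> fraction in [0,1]
    label: str  # "promoter-dominant" | "enhancer-dominant"
    threshold: float
    chosen_d0: float
    radius: float = 1000.0

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "label": self.label,
            "threshold": self.threshold,
            "chosen_d0": self.chosen_d0,
            "radius_bp": self.radius,
        }


def _nearest_tss_distances(peaks: Sequence[Peak], genes: Sequence[GeneAnnotation]) -> np.ndarray:
    """Distance from each peak center to the nearest TSS on its chromosome
    (inf when the chromosome has no annotated TSS)."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}

    out = np.full(len(peaks), np.inf)
    for i, p in enumerate(peaks):
        tss = tss_by_chrom.get(p.chrom)
        if tss is None:
            continue
        j = np.searchsorted(tss, p.center)
        cands = []
        if j < len(tss):
            cands.append(abs(int(tss[j]) - p.center))
        if j > 0:
            cands.append(abs(int(tss[j - 1]) - p.center))
        out[i] = min(cands)
    return out


def fraction_near_tss(
    peaks: Sequence[Peak], genes: Sequence[GeneAnnotation], radius: float = 1000.0
) -> float:
    """Fraction of peaks whose center is within ``radius`` (closed, <=) of
    the nearest TSS of any gene on the same chromosome."""
    if not peaks:
        raise ValueError("fraction_near_tss needs at least one peak")
    d = _nearest_tss_distances(peaks, genes)
    return float(np.mean(d <= radius))


def classify(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    threshold: float = 0.20,
    radius: float = 1000.0,
    d0_override: Optional[float] = None,
) -> ClassificationReport:
    """Classify the cistrome and choose the default decay distance.

    Peaks are sorted by score descending (stable, so equally scored peaks
    keep input-file order; unscored peaks sort below all scored ones).  A
    top-N subset is evaluated only when at least N peaks exist; with no
    scored peaks only the "all" subset is evaluated.  The label is
    promoter-dominant iff any computed fraction is strictly greater than the
    threshold.
    """
    if not peaks:
        raise ValueError("classify needs at least one peak")
    scored = [p for p in peaks if p.score is not None]
    order = sorted(range(len(peaks)),
                   key=lambda i: -(peaks[i].score if peaks[i].score is not None else -np.inf))
    ranked = [peaks[i] for i in order]

    fractions: dict[str, float] = {}
    if scored:
        for n in SUBSET_SIZES:
            if len(peaks) >= n:
                fractions[str(n)] = fraction_near_tss(ranked[:n], genes, radius)
    fractions["all"] = fraction_near_tss(peaks, genes, radius)

    promoter = any(f > threshold for f in fractions.values())
    label = "promoter-dominant" if promoter else "enhancer-dominant"
    default_d0 = PROMOTER_D0 if promoter else ENHANCER_D0
    chosen = float(d0_override) if d0_override is not None else default_d0
    return ClassificationReport(fractions, label, threshold, chosen, radius)
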