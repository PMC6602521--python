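"""The ranked gene list shared by RP scoring, DE integration and enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass
class RankedGeneList:
    """An ordered list of unique gene ids with the score used to order them.

    ``gene_ids`` is the deterministic list order (index 0 = most likely
    direct target; ties broken lexicographically by gene id).  ``ranks``
    carries the mid-rank of every gene (average over ties), which is what
    rank-product arithmetic consumes.  ``higher_is_better`` records the
    direction of ``scores``.
    """

    gene_ids: list
    scores: list
    ranks: pd.Series
    higher_is_better: bool = True

    def __post_init__(self):
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate gene ids in ranking")
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def score_of(self, gene_id) -> float:
        return self.scores[self.gene_ids.index(gene_id)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "score": self.scores,
                "rank": self.ranks.loc[self.gene_ids].values,
            }
        )
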