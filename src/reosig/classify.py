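"""Applying a signature to samples: the majority-vote rule.

A sample votes once per signature pair: the vote counts when ``gene_high``
strictly exceeds ``gene_low`` within the sample (a tie contributes no vote).
Under the default ``at_least_half`` rule the sample is called GC when
2·votes ≥ k; under ``all_pairs`` only when every pair is concordant.  The
rule reads only within-sample orderings of the signature genes, so any
strictly increasing per-sample transform of the abundances — and any change
to non-signature genes — leaves every label unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, RankMatrix
from .signature import Signature

logger = logging.getLogger(__name__)

GC_LABEL = "GC"
NON_GC_LABEL = "non-GC"


@dataclass(frozen=True)
class VoteResult:
    """Per-sample vote outcome.

    ``score`` = votes/k is the continuous score used for ROC analysis;
    ``label`` is None when the sample abstained (signature genes missing).
    """

    sample_id: str
    votes: int
    k: int
    score: float
    label: str | None
    abstained: bool = False

    def __post_init__(self) -> None:
        if not self.abstained:
            if not 0 <= self.votes <= self.k:
                raise ValueError(f"votes {self.votes} outside 0..k={self.k}")


def _decide(votes: int, k: int, vote_rule: str) -> str:
    if vote_rule == "all_pairs":
        return GC_LABEL if votes == k else NON_GC_LABEL
    return GC_LABEL if 2 * votes >= k else NON_GC_LABEL


def vote(
    values: Mapping[str, float] | pd.Series,
    s: Signature,
    sample_id: str = "sample",
) -> VoteResult:
    """Vote a single sample given its abundances (or ranks) by gene.

    Ranks and abundances are interchangeable here: only the strict order of
    the two genes in each pair matters.  Missing signature genes produce an
    abstained result rather than an error.
    """
    values = pd.Series(values) if not isinstance(values, pd.Series) else values
    missing = [g for g in s.genes if g not in values.index]
    if missing:
        logger.warning("sample %s abstains; missing genes %s", sample_id, missing)
        return VoteResult(sample_id, 0, s.k, float("nan"), None, abstained=True)
    votes = sum(
        1 for p in s.pairs if values[p.gene_high] > values[p.gene_low]
    )
    return VoteResult(
        sample_id, votes, s.k, votes / s.k, _decide(votes, s.k, s.vote_rule)
    )


def classify_matrix(
    m: ExpressionMatrix | RankMatrix, s: Signature
) -> list[VoteResult]:
    """Apply the vote rule to every sample of a matrix.

    Deterministic and independent of sample order; samples are returned in
    matrix column order.  If any signature gene is absent from the matrix,
    all samples abstain.
    """
    data = m.ranks if isinstance(m, RankMatrix) else m.data
    missing = [g for g in s.genes if g not in data.index]
    samples = data.columns.tolist()
    if missing:
        logger.warning(
            "all %d samples abstain; matrix lacks signature genes %s",
            len(samples), missing,
        )
        return [
            VoteResult(sid, 0, s.k, float("nan"), None, abstained=True)
            for sid in samples
        ]
    high = data.loc[[p.gene_high for p in s.pairs]].to_numpy()
    low = data.loc[[p.gene_low for p in s.pairs]].to_numpy()
    votes = (high > low).sum(axis=0)
    return [
        VoteResult(sid, int(v), s.k, int(v) / s.k, _decide(int(v), s.k, s.vote_rule))
        for sid, v in zip(samples, votes)
    ]


def results_frame(results: Sequence[VoteResult]) -> pd.DataFrame:
    """Tabulate vote results (sample_id, votes, k, score, label, abstained)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "votes": [r.votes for r in results],
            "k": [r.k for r in results],
            "score": [r.score for r in results],
            "label": [r.label for r in results],
            "abstained": [r.abstained for r in results],
        }
    )


def read_results(path) -> list[VoteResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        VoteResult(
            str(row.sample_id), int(row.votes), int(row.k),
            float(row.score) if np.isfinite(row.score) else float("nan"),
            None if row.abstained else str(row.label),
            bool(row.abstained),
        )
        for row in df.itertuples()
    ]


def write_results(results: Sequence[VoteResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False)
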