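"""Performance evaluation: confusion metrics, Hanley–McNeil AUC, ROC, and
group-wise fold-change / subtraction summaries of signature pairs.

Sensitivity is the proportion of correctly identified GC samples among all
GC samples; specificity the proportion of correctly identified non-GC
samples; accuracy the proportion correct over both groups together.
Adjacent-normal (GC_ADJ) tissue is scored on the GC side by default: a
signature that calls it cancer compensates for inaccurately located
biopsies.

The AUC is the tie-corrected Mann–Whitney probability computed by the
nonparametric Hanley–McNeil method, with its closed-form standard error

    SE² = [A(1−A) + (n⁺−1)(Q₁−A²) + (n⁻−1)(Q₂−A²)] / (n⁺ n⁻),
    Q₁ = A/(2−A),   Q₂ = 2A²/(1+A),

and a 95% confidence interval A ± 1.96·SE clipped to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import GC_LABEL, VoteResult
from .matrix import ClassLabels, ExpressionMatrix, GC_GROUP_CLASSES
from .signature import Signature

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Classification performance of a signature on a labelled cohort."""

    n_gc: int
    n_non: int
    tp: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None
    auc_se: float | None = None
    ci95: tuple[float, float] | None = None
    n_abstained: int = 0

    def summary(self) -> str:
        lines = [
            "Signature evaluation",
            "--------------------",
            f"GC group      n = {self.n_gc:5d}   sensitivity = {format_percent(self.sensitivity)}",
            f"non-GC group  n = {self.n_non:5d}   specificity = {format_percent(self.specificity)}",
            f"overall       n = {self.n_gc + self.n_non:5d}   accuracy    = {format_percent(self.accuracy)}",
        ]
        if self.auc is not None:
            lines.append(
                f"AUC = {self.auc:.4f}  (SE {self.auc_se:.4f}, "
                f"95% CI {self.ci95[0]:.4f}-{self.ci95[1]:.4f})"
            )
        if self.n_abstained:
            lines.append(f"abstained: {self.n_abstained}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "n_gc": self.n_gc, "n_non": self.n_non,
            "tp": self.tp, "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_abstained": self.n_abstained,
        }
        if self.auc is not None:
            d.update(auc=self.auc, auc_se=self.auc_se,
                     ci95_low=self.ci95[0], ci95_high=self.ci95[1])
        return d


def format_percent(fraction: float) -> str:
    """Display a fraction as a percentage with two decimals (e.g. '96.20%')."""
    return f"{fraction * 100:.2f}%"


def _truth_is_gc(truth: ClassLabels, sample_id: str, gc_adj_as_gc: bool) -> bool:
    cls = truth.labels[sample_id]
    if gc_adj_as_gc:
        return cls in GC_GROUP_CLASSES
    return cls == "GC"


def confusion_metrics(
    results: Sequence[VoteResult],
    truth: ClassLabels,
    gc_adj_as_gc: bool = True,
) -> EvalReport:
    """Sensitivity, specificity and accuracy of vote results against truth.

    Abstentions are excluded from the counts and reported separately.  With
    ``gc_adj_as_gc`` (default) adjacent-normal samples belong to the GC truth
    group; set it False to score them as non-GC instead.
    """
    tp = tn = n_gc = n_non = n_abs = 0
    for r in results:
        if r.sample_id not in truth.labels.index:
            raise KeyError(f"no truth label for sample {r.sample_id!r}")
        if r.abstained:
            n_abs += 1
            continue
        is_gc = _truth_is_gc(truth, r.sample_id, gc_adj_as_gc)
        if is_gc:
            n_gc += 1
            tp += r.label == GC_LABEL
        else:
            n_non += 1
            tn += r.label != GC_LABEL
    if n_gc == 0 or n_non == 0:
        raise ValueError(
            f"both truth groups must be non-empty (GC {n_gc}, non-GC {n_non})"
        )
    return EvalReport(
        n_gc=n_gc, n_non=n_non, tp=tp, tn=tn,
        sensitivity=tp / n_gc,
        specificity=tn / n_non,
        accuracy=(tp + tn) / (n_gc + n_non),
        n_abstained=n_abs,
    )


def hanley_mcneil_auc(
    scores: Sequence[float], truth: Sequence[bool]
) -> tuple[float, float, tuple[float, float]]:
    """Nonparametric AUC with Hanley–McNeil standard error and 95% CI.

    ``truth`` flags the positive (GC) samples.  The AUC is the Mann–Whitney
    probability: over all (positive, negative) sample pairs, a strictly
    higher positive score counts 1, a tie 0.5.  Computed via midranks in
    O(n log n); identical to the explicit pairwise count.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative class")
    ranks = scipy.stats.rankdata(scores)
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    ci = (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))
    return float(auc), float(se), ci


def roc_points(
    scores: Sequence[float], truth: Sequence[bool]
) -> pd.DataFrame:
    """ROC operating points swept over the distinct score values.

    Returns (threshold, fpr, tpr) rows, monotone nondecreasing in both
    coordinates; the trapezoidal area under them equals the Mann–Whitney
    AUC, ties handled consistently.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs both a positive and a negative class")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores, drop_intermediate=False)
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def trapezoidal_auc(points: pd.DataFrame) -> float:
    return float(np.trapezoid(points["tpr"].to_numpy(), points["fpr"].to_numpy()))


def evaluate_results(
    results: Sequence[VoteResult],
    truth: ClassLabels,
    gc_adj_as_gc: bool = True,
) -> EvalReport:
    """Full report: confusion metrics plus Hanley–McNeil AUC on votes/k scores."""
    report = confusion_metrics(results, truth, gc_adj_as_gc)
    active = [r for r in results if not r.abstained]
    scores = [r.score for r in active]
    flags = [_truth_is_gc(truth, r.sample_id, gc_adj_as_gc) for r in active]
    report.auc, report.auc_se, report.ci95 = hanley_mcneil_auc(scores, flags)
    return report


@dataclass
class GroupPairSummary:
    """Median fold change and median difference of a pair within one group.

    Quantitative summaries like these vary widely across platforms and
    cohorts even when the qualitative ordering is perfectly stable — which
    is the argument for voting on orderings rather than on magnitudes.
    """

    gene_high: str
    gene_low: str
    group: str
    n: int
    median_fold_change: float
    median_difference: float
    n_skipped_fc: int = 0


def group_pair_summaries(
    m: ExpressionMatrix,
    truth: ClassLabels,
    s: Signature,
    groups: dict[str, Sequence[str]] | None = None,
) -> list[GroupPairSummary]:
    """Per signature pair and sample group, median gene_high/gene_low fold
    change and median gene_high − gene_low difference.

    Default groups: GC, non-GC (normal + gastritis + intestinal metaplasia)
    and GC_ADJ.  Samples with a zero denominator are skipped for the fold
    change (with a logged count) but kept for the difference.
    """
    missing = [g for g in s.genes if g not in m.data.index]
    if missing:
        raise KeyError(f"matrix lacks signature genes: {missing}")
    if groups is None:
        groups = {
            "GC": truth.samples_of("GC"),
            "non-GC": truth.non_gc_samples(),
            "GC_ADJ": truth.samples_of("GC_ADJ"),
        }
    out: list[GroupPairSummary] = []
    for pair in s.pairs:
        high = m.data.loc[pair.gene_high]
        low = m.data.loc[pair.gene_low]
        for group, samples in groups.items():
            samples = [sid for sid in samples if sid in m.data.columns]
            if not samples:
                continue
            h = high[samples].to_numpy()
            l = low[samples].to_numpy()
            nonzero = l != 0
            n_skip = int((~nonzero).sum())
            if n_skip:
                logger.info(
                    "group %s pair %s/%s: %d zero-denominator samples skipped "
                    "for fold change", group, pair.gene_high, pair.gene_low, n_skip,
                )
            fc = float(np.median(h[nonzero] / l[nonzero])) if nonzero.any() else float("nan")
            out.append(
                GroupPairSummary(
                    pair.gene_high, pair.gene_low, group, len(samples),
                    fc, float(np.median(h - l)), n_skip,
                )
            )
    return out


def summaries_frame(summaries: Sequence[GroupPairSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_high": [x.gene_high for x in summaries],
            "gene_low": [x.gene_low for x in summaries],
            "group": [x.group for x in summaries],
            "n": [x.n for x in summaries],
            "median_fold_change": [x.median_fold_change for x in summaries],
            "median_difference": [x.median_difference for x in summaries],
            "n_skipped_fc": [x.n_skipped_fc for x in summaries],
        }
    )
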