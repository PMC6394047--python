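"""Signature discovery as a model fit.

:class:`ReoSignatureModel` holds training data (a gene × sample abundance
matrix and class labels) and the discovery parameters; :meth:`fit` runs the
whole procedure — within-sample ranking, per-class stable-pair mining,
non-GC consensus, reversal detection, reversal-degree scoring, top-k sweep
and parsimonious selection — and returns a :class:`ReoSignatureResults`
object carrying the selected signature, the ordered reversal pairs, per-k
training accuracies, and prediction/evaluation/summary methods.

Reversal degree
---------------
For a reversal pair (i, j) the absolute rank difference in a sample is
Rij = |Ri − Rj|.  With mean[Rij(non)] and mean[Rij(gc)] the class means over
non-GC and GC training samples, the reversal degree is their geometric mean

    avgRij = sqrt(mean[Rij(non)] × mean[Rij(gc)]),

larger meaning more strongly reversed.  Pairs are sorted by descending
degree, the top-k prefixes are scored by training accuracy under the vote
rule, and the smallest k attaining the maximum accuracy is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .classify import VoteResult, classify_matrix
from .matrix import ClassLabels, ExpressionMatrix, RankMatrix, rank_transform
from .metrics import EvalReport, evaluate_results, format_percent
from .pairs import (
    ReversalCandidate,
    StablePairSet,
    consensus_stable_pairs,
    reversal_pairs,
    stable_pairs,
)
from .signature import Signature, SignaturePair

__all__ = [
    "ReversalPair",
    "rank_difference",
    "reversal_degree",
    "order_by_degree",
    "sweep_topk",
    "select_signature",
    "ReoSignatureModel",
    "ReoSignatureResults",
]


@dataclass(frozen=True)
class ReversalPair:
    """A reversal pair scored by its reversal degree.

    The orientation stored is the GC one.  ``degree`` is the geometric mean
    of the class-wise mean absolute rank differences and always lies between
    them.
    """

    gene_high: str
    gene_low: str
    mean_rankdiff_non: float
    mean_rankdiff_gc: float
    degree: float
    support_non: float | None = None
    support_gc: float | None = None

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("reversal degree cannot be negative")


def rank_difference(r: RankMatrix, gene_a: str, gene_b: str, sample: str) -> float:
    """|rank(gene_a) − rank(gene_b)| within one sample."""
    for g in (gene_a, gene_b):
        if g not in r.ranks.index:
            raise KeyError(f"gene {g!r} not in rank matrix")
    if sample not in r.ranks.columns:
        raise KeyError(f"sample {sample!r} not in rank matrix")
    return float(abs(r.ranks.at[gene_a, sample] - r.ranks.at[gene_b, sample]))


def _mean_absdiff(r: RankMatrix, gene_a: str, gene_b: str, samples: Sequence[str]) -> float:
    sub = r.ranks.loc[[gene_a, gene_b], list(samples)].to_numpy()
    return float(np.abs(sub[0] - sub[1]).mean())


def reversal_degree(
    r: RankMatrix,
    labels: ClassLabels,
    pair,
    non_classes: Sequence[str] = ("NORMAL", "GASTRITIS"),
) -> ReversalPair:
    """Score one GC-oriented pair by its reversal degree.

    ``pair`` may be a :class:`ReversalCandidate` or any object with
    ``gene_high``/``gene_low``.  Mean absolute rank differences are taken
    over the non-GC training samples (``non_classes``) and the GC samples.
    """
    non = labels.samples_of(*non_classes)
    gc = labels.samples_of("GC")
    if not non or not gc:
        raise ValueError("both the non-GC and GC training classes must be non-empty")
    mean_non = _mean_absdiff(r, pair.gene_high, pair.gene_low, non)
    mean_gc = _mean_absdiff(r, pair.gene_high, pair.gene_low, gc)
    return ReversalPair(
        pair.gene_high,
        pair.gene_low,
        mean_non,
        mean_gc,
        math.sqrt(mean_non * mean_gc),
        getattr(pair, "support_non", None),
        getattr(pair, "support_gc", None),
    )


def order_by_degree(pairs: Sequence[ReversalPair]) -> list[ReversalPair]:
    """Sort descending by degree; ties broken by (gene_high, gene_low)."""
    return sorted(pairs, key=lambda p: (-p.degree, p.gene_high, p.gene_low))


def _signature_from(ordered: Sequence[ReversalPair], k: int, vote_rule: str) -> Signature:
    return Signature(
        pairs=[SignaturePair(p.gene_high, p.gene_low) for p in ordered[:k]],
        vote_rule=vote_rule,
    )


def sweep_topk(
    ordered: Sequence[ReversalPair],
    r: RankMatrix,
    labels: ClassLabels,
    k_max: int | None = None,
    vote_rule: str = "at_least_half",
    non_classes: Sequence[str] = ("NORMAL", "GASTRITIS"),
) -> np.ndarray:
    """Training accuracy of the top-k signature for each k = 1..k_max.

    Accuracy is unweighted over the pooled GC and non-GC training samples.
    """
    if k_max is None:
        k_max = len(ordered)
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if k_max > len(ordered):
        raise ValueError(f"k_max {k_max} exceeds the {len(ordered)} reversal pairs")
    gc = set(labels.samples_of("GC"))
    non = set(labels.samples_of(*non_classes))
    train = sorted(gc | non)
    sub = RankMatrix(r.ranks[train])
    accuracies = np.empty(k_max)
    for k in range(1, k_max + 1):
        sig = _signature_from(ordered, k, vote_rule)
        results = classify_matrix(sub, sig)
        correct = sum(
            (res.label == "GC") == (res.sample_id in gc) for res in results
        )
        accuracies[k - 1] = correct / len(train)
    return accuracies


def select_signature(
    accuracies: Sequence[float],
    ordered: Sequence[ReversalPair],
    vote_rule: str = "at_least_half",
) -> Signature:
    """Pick the smallest k attaining the maximum training accuracy."""
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size == 0:
        raise ValueError("empty accuracy vector")
    k_star = int(np.argmax(accuracies)) + 1  # argmax returns the first maximum
    sig = _signature_from(ordered, k_star, vote_rule)
    sig.training_accuracy = float(accuracies[k_star - 1])
    return sig


class ReoSignatureModel:
    """Reversal-gene-pair signature discovery on labelled training data.

    Parameters
    ----------
    matrix
        Gene × sample abundance matrix (any units; only within-sample
        orderings are used).
    labels
        Class per sample.  Training uses the GC class against the classes in
        ``non_gc_classes`` (default normal + gastritis, the classes defining
        the non-GC consensus); adjacent-normal tissue never enters training.
    threshold
        Stability fraction; a pair's ordering must hold in at least this
        fraction of a class's samples (strict inequalities, exact rational
        comparison).  Default 99/100.
    k_max
        Largest signature size swept; default: all reversal pairs found.
    vote_rule
        'at_least_half' (default) or 'all_pairs'.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        labels: ClassLabels,
        threshold=Fraction(99, 100),
        k_max: int | None = None,
        vote_rule: str = "at_least_half",
        non_gc_classes: Sequence[str] = ("NORMAL", "GASTRITIS"),
    ) -> None:
        labels.check_cover(matrix)
        self.matrix = matrix
        self.labels = labels
        self.threshold = threshold
        self.k_max = k_max
        self.vote_rule = vote_rule
        self.non_gc_classes = tuple(non_gc_classes)

    @classmethod
    def from_files(cls, matrix_path, labels_path, **kwargs) -> "ReoSignatureModel":
        from .matrix import read_class_labels, read_expression_matrix

        return cls(
            read_expression_matrix(matrix_path),
            read_class_labels(labels_path),
            **kwargs,
        )

    def fit(self) -> "ReoSignatureResults":
        """Run the full discovery procedure and return results."""
        ranks = rank_transform(self.matrix)
        per_class = {
            cls: stable_pairs(ranks, self.labels, cls, self.threshold)
            for cls in self.non_gc_classes
        }
        non_gc = consensus_stable_pairs(*per_class.values())
        gc = stable_pairs(ranks, self.labels, "GC", self.threshold)
        candidates = reversal_pairs(non_gc, gc)
        if not candidates:
            raise ValueError(
                "no reversal pairs at the given stability threshold; "
                "nothing to build a signature from"
            )
        scored = [
            reversal_degree(ranks, self.labels, c, self.non_gc_classes)
            for c in candidates
        ]
        ordered = order_by_degree(scored)
        k_max = self.k_max if self.k_max is not None else len(ordered)
        accuracies = sweep_topk(
            ordered, ranks, self.labels, k_max, self.vote_rule, self.non_gc_classes
        )
        signature = select_signature(accuracies, ordered, self.vote_rule)
        return ReoSignatureResults(
            model=self,
            ranks=ranks,
            stable_sets=per_class,
            non_gc_consensus=non_gc,
            gc_stable=gc,
            reversal_pairs_=ordered,
            accuracies=accuracies,
            signature=signature,
        )


@dataclass
class ReoSignatureResults:
    """Fitted signature plus everything the discovery produced."""

    model: ReoSignatureModel
    ranks: RankMatrix
    stable_sets: dict[str, StablePairSet]
    non_gc_consensus: StablePairSet
    gc_stable: StablePairSet
    reversal_pairs_: list[ReversalPair]
    accuracies: np.ndarray
    signature: Signature

    @property
    def k(self) -> int:
        return self.signature.k

    @property
    def training_accuracy(self) -> float:
        return float(self.signature.training_accuracy)

    def predict(self, matrix: ExpressionMatrix | RankMatrix) -> list[VoteResult]:
        """Classify the samples of a matrix with the fitted signature."""
        return classify_matrix(matrix, self.signature)

    def evaluate(
        self,
        matrix: ExpressionMatrix | RankMatrix,
        truth: ClassLabels,
        gc_adj_as_gc: bool = True,
    ) -> EvalReport:
        """Classify a labelled cohort and report the full metric set."""
        return evaluate_results(self.predict(matrix), truth, gc_adj_as_gc)

    def summary(self) -> str:
        """Plain-text account of the fit, statsmodels-style."""
        m = self.model
        lines = [
            "Reversal-pair signature discovery",
            "=================================",
            f"samples: {m.matrix.n_samples}   genes: {m.matrix.n_genes}   "
            f"training classes: {' + '.join(m.non_gc_classes)} vs GC",
            f"stability threshold: {Fraction(str(m.threshold)) if not isinstance(m.threshold, Fraction) else m.threshold}",
        ]
        for cls, s in self.stable_sets.items():
            lines.append(f"stable pairs [{cls}]: {len(s)}")
        lines.append(f"stable pairs [GC]: {len(self.gc_stable)}")
        lines.append(f"non-GC consensus pairs: {len(self.non_gc_consensus)}")
        lines.append(f"reversal pairs: {len(self.reversal_pairs_)}")
        lines.append("")
        lines.append("rank  gene_high  gene_low   avgRij   mean(non)  mean(GC)")
        for i, p in enumerate(self.reversal_pairs_, 1):
            marker = "*" if i <= self.signature.k else " "
            lines.append(
                f"{marker}{i:3d}  {p.gene_high:<9s}  {p.gene_low:<9s}"
                f"  {p.degree:7.2f}  {p.mean_rankdiff_non:9.2f}  {p.mean_rankdiff_gc:8.2f}"
            )
        lines.append("")
        accs = "  ".join(
            f"k={k}: {format_percent(a)}" for k, a in enumerate(self.accuracies, 1)
        )
        lines.append(f"training accuracy by k:  {accs}")
        lines.append(
            f"selected k* = {self.signature.k} "
            f"(training accuracy {format_percent(self.training_accuracy)}, "
            f"vote rule {self.signature.vote_rule})"
        )
        return "\n".join(lines)
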