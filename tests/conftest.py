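"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by the most direct route
available — exhaustive double loops, explicit pairwise counts — so the
vectorised implementations are checked against code that cannot share their
failure modes.
"""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from reosig import ClassLabels, ExpressionMatrix


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def stable_pairs_oracle(ranks_df: pd.DataFrame, samples, threshold) -> set:
    """Exhaustive double-loop stable-pair miner.

    Returns {(gene_high, gene_low)} using strict comparisons, ties counting
    toward neither orientation, and exact rational threshold comparison.
    """
    thr = threshold if isinstance(threshold, Fraction) else Fraction(str(threshold))
    n = len(samples)
    genes = list(ranks_df.index)
    out = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gt = lt = 0
            for s in samples:
                a = ranks_df.at[genes[i], s]
                b = ranks_df.at[genes[j], s]
                if a > b:
                    gt += 1
                elif a < b:
                    lt += 1
            if gt * thr.denominator >= thr.numerator * n:
                out.add((genes[i], genes[j]))
            if lt * thr.denominator >= thr.numerator * n:
                out.add((genes[j], genes[i]))
    return out


def mann_whitney_oracle(scores, truth) -> float:
    """Explicit all-pairs AUC count: 1 per win, 0.5 per tie."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with a clean ordering in both samples."""
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [5.0, 2.0, 9.0], "s2": [6.0, 3.0, 10.0]},
            index=["gA", "gB", "gC"],
        )
    )


@pytest.fixture
def labeled_matrix() -> tuple[ExpressionMatrix, ClassLabels]:
    """2 genes x 8 samples: g1 > g2 in every GC sample, reversed elsewhere."""
    rng = np.random.default_rng(42)
    cols = {}
    labels = {}
    for i in range(4):
        lo, hi = sorted(rng.uniform(1, 10, size=2))
        cols[f"n{i}"] = [lo, hi]
        labels[f"n{i}"] = "NORMAL" if i % 2 == 0 else "GASTRITIS"
    for i in range(4):
        lo, hi = sorted(rng.uniform(1, 10, size=2))
        cols[f"t{i}"] = [hi, lo]
        labels[f"t{i}"] = "GC"
    m = ExpressionMatrix(pd.DataFrame(cols, index=["g1", "g2"]))
    return m, ClassLabels(pd.Series(labels))


@pytest.fixture
def random_labeled_matrix():
    """Factory: G genes x N samples of random abundances with random labels."""

    def make(n_genes=10, n_samples=20, seed=0, classes=("NORMAL", "GASTRITIS", "GC")):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.lognormal(3.0, 1.0, size=(n_genes, n_samples)),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{i:03d}" for i in range(n_samples)],
        )
        lab = pd.Series(
            [classes[i % len(classes)] for i in range(n_samples)],
            index=data.columns,
        )
        return ExpressionMatrix(data), ClassLabels(lab)

    return make
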