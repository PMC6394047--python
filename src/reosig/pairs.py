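"""Stable-pair mining, consensus pairs and reversal-pair detection.

A gene pair is *stable* in a tissue class when the same within-sample
ordering (Gi > Gj or Gi < Gj, strictly) holds in at least a stated fraction
of the class's samples — 99% in the published analysis.  Pairs stable with
the same orientation in every non-cancer class form the *consensus* non-GC
set; pairs stable in both the non-GC consensus and the GC class but with
opposite orientations are *reversal pairs*, the diagnostic units.

Ties (equal measured abundance, hence equal average ranks) count toward
neither orientation: the definitions use strict inequalities only.  The
stability threshold is compared with exact rational arithmetic so that, for
example, 99% of 23 samples unambiguously requires all 23.

Internally a :class:`StablePairSet` stores index arrays over a fixed gene
universe, so all-pairs scans over hundreds of genes stay vectorised; the
object still iterates as :class:`OrientedPair` records.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

import numpy as np

from .matrix import ClassLabels, RankMatrix

__all__ = [
    "OrientedPair",
    "StablePairSet",
    "ReversalCandidate",
    "stable_pairs",
    "consensus_stable_pairs",
    "reversal_pairs",
]


@dataclass(frozen=True)
class OrientedPair:
    """An oriented pair with its support in the class examined.

    ``support`` is the fraction of the class's samples in which
    ``gene_high`` ranks strictly above ``gene_low``.
    """

    gene_high: str
    gene_low: str
    support: float

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise ValueError(f"pair cannot relate a gene to itself: {self.gene_high}")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support out of [0,1]: {self.support}")


def _as_fraction(threshold) -> Fraction:
    """Exact rational form of a stability threshold.

    Floats are converted through their shortest decimal representation, so a
    user-supplied 0.99 becomes exactly 99/100 rather than the nearest binary
    float; the stability test is then pure integer arithmetic.
    """
    if isinstance(threshold, Fraction):
        frac = threshold
    else:
        frac = Fraction(str(threshold))
    if not Fraction(1, 2) < frac <= 1:
        raise ValueError(f"threshold must lie in (0.5, 1], got {threshold}")
    return frac


class StablePairSet:
    """Set of stable oriented pairs over a fixed gene universe.

    At most one orientation per unordered pair can be present (guaranteed by
    thresholds above 1/2).  Iteration yields :class:`OrientedPair`.
    """

    def __init__(
        self,
        class_tag: str,
        threshold,
        gene_ids: Sequence[str],
        high_idx: np.ndarray,
        low_idx: np.ndarray,
        support: np.ndarray,
    ) -> None:
        self.class_tag = class_tag
        self.threshold = _as_fraction(threshold)
        self.gene_ids = tuple(gene_ids)
        self.high_idx = np.asarray(high_idx, dtype=np.int64)
        self.low_idx = np.asarray(low_idx, dtype=np.int64)
        self.support = np.asarray(support, dtype=float)
        if not (len(self.high_idx) == len(self.low_idx) == len(self.support)):
            raise ValueError("pair arrays must have equal length")
        if len(self.support) and self.support.min() < float(self.threshold) - 1e-12:
            raise ValueError("pair support below the set's threshold")

    @classmethod
    def from_pairs(
        cls, class_tag: str, threshold, gene_ids: Sequence[str],
        pairs: Iterable[OrientedPair],
    ) -> "StablePairSet":
        index = {g: i for i, g in enumerate(gene_ids)}
        pairs = list(pairs)
        return cls(
            class_tag,
            threshold,
            gene_ids,
            np.array([index[p.gene_high] for p in pairs], dtype=np.int64),
            np.array([index[p.gene_low] for p in pairs], dtype=np.int64),
            np.array([p.support for p in pairs], dtype=float),
        )

    def __len__(self) -> int:
        return len(self.high_idx)

    def __iter__(self) -> Iterator[OrientedPair]:
        for h, l, s in zip(self.high_idx, self.low_idx, self.support):
            yield OrientedPair(self.gene_ids[h], self.gene_ids[l], float(s))

    @property
    def pairs(self) -> frozenset[OrientedPair]:
        return frozenset(self)

    def orientations(self) -> set[tuple[str, str]]:
        """The (gene_high, gene_low) tuples, without supports."""
        return {
            (self.gene_ids[h], self.gene_ids[l])
            for h, l in zip(self.high_idx, self.low_idx)
        }

    # canonical integer keys: unordered pair id plus orientation sign -------
    def _keys_signs(self) -> tuple[np.ndarray, np.ndarray]:
        g = len(self.gene_ids)
        lo = np.minimum(self.high_idx, self.low_idx)
        hi = np.maximum(self.high_idx, self.low_idx)
        keys = lo * np.int64(g) + hi
        signs = np.where(self.high_idx == lo, np.int8(1), np.int8(-1))
        order = np.argsort(keys)
        return keys[order], signs[order], order  # type: ignore[return-value]


def _class_samples(labels: ClassLabels, cls, ranks: RankMatrix) -> list[str]:
    classes = (cls,) if isinstance(cls, str) else tuple(cls)
    samples = [s for s in labels.samples_of(*classes) if s in set(ranks.sample_ids)]
    return samples


def stable_pairs(
    r: RankMatrix,
    labels: ClassLabels,
    cls,
    threshold=Fraction(99, 100),
    candidates: Iterable[tuple[str, str]] | None = None,
    block_size: int = 128,
) -> StablePairSet:
    """Mine stable oriented pairs of a class.

    A pair is emitted with orientation ``gene_high > gene_low`` iff the
    strict rank inequality in that direction holds in at least ``threshold``
    of the class's samples (integer cross-multiplied comparison).  With
    ``candidates`` given, only those unordered pairs are scanned; otherwise
    all G(G−1)/2 pairs are, in blocks of rows to bound memory.

    Parameters
    ----------
    cls
        A class name, or a sequence of class names whose samples are pooled
        (within-sample orderings need no cross-sample normalisation).
    """
    frac = _as_fraction(threshold)
    samples = _class_samples(labels, cls, r)
    if len(samples) < 2:
        raise ValueError(f"class {cls!r} needs at least 2 samples, found {len(samples)}")
    tag = cls if isinstance(cls, str) else "+".join(cls)
    R = r.ranks[samples].to_numpy()
    g, n = R.shape
    # integer pass condition: count/n >= num/den  <=>  count*den >= num*n
    need = frac.numerator * n
    den = frac.denominator
    gene_ids = r.gene_ids

    highs: list[np.ndarray] = []
    lows: list[np.ndarray] = []
    sups: list[np.ndarray] = []

    if candidates is not None:
        index = {gid: i for i, gid in enumerate(gene_ids)}
        cand = [(index[a], index[b]) for a, b in candidates]
        if not cand:
            return StablePairSet(tag, frac, gene_ids, [], [], [])
        ii = np.array([c[0] for c in cand], dtype=np.int64)
        jj = np.array([c[1] for c in cand], dtype=np.int64)
        gt = (R[ii] > R[jj]).sum(axis=1)
        lt = (R[ii] < R[jj]).sum(axis=1)
        m_gt = gt * den >= need
        m_lt = lt * den >= need
        highs = [ii[m_gt], jj[m_lt]]
        lows = [jj[m_gt], ii[m_lt]]
        sups = [gt[m_gt] / n, lt[m_lt] / n]
    else:
        for start in range(0, g, block_size):
            stop = min(start + block_size, g)
            block = R[start:stop]                      # (b, n)
            gt = (block[:, None, :] > R[None, :, :]).sum(axis=2)   # (b, g)
            lt = (block[:, None, :] < R[None, :, :]).sum(axis=2)
            rows, cols = np.indices(gt.shape)
            rows = rows + start
            upper = cols > rows                         # each unordered pair once
            m_gt = upper & (gt * den >= need)
            m_lt = upper & (lt * den >= need)
            highs.extend([rows[m_gt], cols[m_lt]])
            lows.extend([cols[m_gt], rows[m_lt]])
            sups.extend([gt[m_gt] / n, lt[m_lt] / n])

    high_idx = np.concatenate(highs) if highs else np.empty(0, dtype=np.int64)
    low_idx = np.concatenate(lows) if lows else np.empty(0, dtype=np.int64)
    support = np.concatenate(sups) if sups else np.empty(0, dtype=float)
    return StablePairSet(tag, frac, gene_ids, high_idx, low_idx, support)


def consensus_stable_pairs(*sets: StablePairSet) -> StablePairSet:
    """Pairs stable with identical orientation in every input set.

    Support is recorded as the minimum across inputs.  All inputs must share
    one gene universe; otherwise intersect genes before mining.
    """
    if len(sets) < 2:
        raise ValueError("consensus needs at least 2 stable-pair sets")
    universe = sets[0].gene_ids
    for s in sets[1:]:
        if s.gene_ids != universe:
            raise ValueError(
                "stable-pair sets are over different gene universes; "
                "restrict matrices with intersect_genes before mining"
            )

    keys, signs, order = sets[0]._keys_signs()
    support = sets[0].support[order]
    for s in sets[1:]:
        k2, s2, o2 = s._keys_signs()
        sup2 = s.support[o2]
        common, ia, ib = np.intersect1d(keys, k2, return_indices=True)
        same = signs[ia] == s2[ib]
        keys = common[same]
        signs = signs[ia][same]
        support = np.minimum(support[ia], sup2[ib])[same]

    g = len(universe)
    lo = keys // g
    hi = keys % g
    high_idx = np.where(signs == 1, lo, hi)
    low_idx = np.where(signs == 1, hi, lo)
    tag = "&".join(s.class_tag for s in sets)
    threshold = min(s.threshold for s in sets)
    return StablePairSet(tag, threshold, universe, high_idx, low_idx, support)


@dataclass(frozen=True)
class ReversalCandidate:
    """A reversal pair in its GC orientation, with class-wise supports.

    ``gene_high``/``gene_low`` give the orientation held in the cancer
    class; the non-GC consensus holds the opposite one.
    """

    gene_high: str
    gene_low: str
    support_non: float
    support_gc: float


def reversal_pairs(non_gc: StablePairSet, gc: StablePairSet) -> list[ReversalCandidate]:
    """Pairs stable in both sets with opposite orientations.

    Results carry the GC orientation.  Ordered deterministically by
    (gene_high, gene_low).
    """
    if non_gc.gene_ids != gc.gene_ids:
        raise ValueError(
            "stable-pair sets are over different gene universes; "
            "restrict matrices with intersect_genes before mining"
        )
    k1, s1, o1 = non_gc._keys_signs()
    k2, s2, o2 = gc._keys_signs()
    sup1 = non_gc.support[o1]
    sup2 = gc.support[o2]
    common, ia, ib = np.intersect1d(k1, k2, return_indices=True)
    opposite = s1[ia] != s2[ib]
    keys = common[opposite]
    gc_signs = s2[ib][opposite]
    sup_non = sup1[ia][opposite]
    sup_gc = sup2[ib][opposite]

    g = len(gc.gene_ids)
    lo = keys // g
    hi = keys % g
    high_idx = np.where(gc_signs == 1, lo, hi)
    low_idx = np.where(gc_signs == 1, hi, lo)
    out = [
        ReversalCandidate(
            gc.gene_ids[h], gc.gene_ids[l], float(sn), float(sg)
        )
        for h, l, sn, sg in zip(high_idx, low_idx, sup_non, sup_gc)
    ]
    out.sort(key=lambda c: (c.gene_high, c.gene_low))
    return out
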