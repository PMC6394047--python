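"""Expression matrices, class labels, probe collapsing and within-sample ranks.

The central objects of the package are the gene × sample abundance table
(:class:`ExpressionMatrix`) and its within-sample rank transform
(:class:`RankMatrix`).  Every downstream quantity — pair stability, reversal
degree, the majority vote — depends on the data only through the within-sample
ordering of genes, which is what makes the method immune to monotone
per-sample measurement distortions (platform, lab and batch effects).

Ranks are ascending (rank 1 = lowest abundance) and ties receive the average
of the tied rank positions.  The direction is an internal convention only:
absolute rank differences and all order comparisons are symmetric in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

#: Closed vocabulary of sample classes.
CLASSES = ("NORMAL", "GASTRITIS", "IM", "GC", "GC_ADJ")

#: Classes forming the non-cancer group at evaluation time.
NON_GC_CLASSES = ("NORMAL", "GASTRITIS", "IM")

#: Classes scored as cancer at evaluation time.  Adjacent-normal tissue is
#: scored on the cancer side: calling it GC models the clinically relevant
#: case of an inaccurately located biopsy.
GC_GROUP_CLASSES = ("GC", "GC_ADJ")


@dataclass
class ExpressionMatrix:
    """A validated gene × sample abundance table.

    Parameters
    ----------
    data
        DataFrame with unique gene identifiers as index and unique sample
        identifiers as columns; all values finite and non-negative.
    batch
        Optional per-sample batch/platform tag, indexed by sample id.
    """

    data: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        neg = values < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {values[g, s]} at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.batch is not None:
            self.batch = self.batch.reindex(self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[genes], self.batch)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
        batch = self.batch[samples] if self.batch is not None else None
        return ExpressionMatrix(self.data[samples], batch)


@dataclass
class RankMatrix:
    """Within-sample ranks of genes (ascending, average ties).

    Per sample the rank sum is always G(G+1)/2 — the average-rank tie policy
    preserves it — and without ties the ranks are a permutation of 1..G.
    """

    ranks: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return self.ranks.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.ranks.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[1]


@dataclass
class ClassLabels:
    """Sample → class assignment over the closed class vocabulary."""

    labels: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(CLASSES)
        if bad:
            raise ValueError(
                f"unknown classes {sorted(bad)}; allowed: {list(CLASSES)}"
            )
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers in labels: {dups[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.index.tolist()

    def samples_of(self, *classes: str) -> list[str]:
        for cls in classes:
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
        mask = self.labels.isin(classes)
        return self.labels.index[mask].tolist()

    def gc_samples(self, include_adjacent: bool = True) -> list[str]:
        classes = GC_GROUP_CLASSES if include_adjacent else ("GC",)
        return self.samples_of(*classes)

    def non_gc_samples(self) -> list[str]:
        return self.samples_of(*NON_GC_CLASSES)

    def check_cover(self, matrix: ExpressionMatrix) -> None:
        """Require that every labeled sample exists in *matrix*."""
        missing = set(self.labels.index) - set(matrix.sample_ids)
        if missing:
            raise ValueError(
                f"labeled samples absent from matrix: {sorted(missing)[:5]}"
            )


@dataclass
class ProbeMap:
    """Many-to-one probe → gene mapping (each probe maps to exactly one gene)."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, batch_tag: str | None = None) -> ExpressionMatrix:
    """Read a tab-separated gene × sample matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate gene rows are rejected (probe collapsing is explicit via
    :func:`collapse_probes`), as are duplicate sample columns, non-numeric
    cells and negative values — each with row/column context in the message.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValueError(f"duplicate sample identifier in header: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows: {dups[:5]}")
    try:
        numeric = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.at[gene, sample])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {sample!r}: "
                        f"{df.at[gene, sample]!r}"
                    ) from None
        raise
    numeric.index.name = None
    batch = None
    if batch_tag is not None:
        batch = pd.Series(batch_tag, index=numeric.columns)
    m = ExpressionMatrix(numeric, batch)
    logger.info(
        "read %d genes x %d samples from %s", m.n_genes, m.n_samples, path
    )
    return m


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_class_labels(path) -> ClassLabels:
    """Read a two-column (sample_id, class) tab-separated label table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, class)")
    series = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="class"
    )
    labels = ClassLabels(series)
    logger.info("read %d sample labels from %s", len(series), path)
    return labels


def write_class_labels(labels: ClassLabels, path) -> None:
    df = pd.DataFrame(
        {"sample_id": labels.labels.index, "class": labels.labels.to_numpy()}
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> ProbeMap:
    """Read a two-column (probe_id, gene_id) tab-separated mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe_id, gene_id)")
    probes = df.iloc[:, 0]
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].tolist()
        raise ValueError(f"probe mapped to more than one gene: {dups[:5]}")
    return ProbeMap(dict(zip(probes, df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def collapse_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-keyed matrix to genes by the arithmetic mean.

    When several probes map to one gene, the gene's value per sample is the
    arithmetic mean of those probes' values.  Probes absent from the map are
    dropped (with a logged count); an empty probe/map intersection is an
    error.  Output genes are sorted by identifier for determinism.
    """
    mapped = m.data.index.map(lambda p: pm.entries.get(p))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no probe in the matrix is present in the probe map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    collapsed = m.data.loc[keep].groupby(mapped[keep]).mean()
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, m.batch)


def rank_transform(m: ExpressionMatrix) -> RankMatrix:
    """Rank genes within each sample (ascending, average ties).

    Ranks are computed independently per sample over the full gene set of the
    matrix at hand.  Any strictly increasing per-sample transform of the
    abundances leaves the output bit-identical.
    """
    if m.n_genes < 2:
        raise ValueError("rank_transform needs at least 2 genes")
    ranks = scipy.stats.rankdata(m.data.to_numpy(), method="average", axis=0)
    return RankMatrix(pd.DataFrame(ranks, index=m.data.index, columns=m.data.columns))


def intersect_genes(*matrices: ExpressionMatrix) -> list[ExpressionMatrix]:
    """Restrict matrices to their common gene set (sorted by identifier).

    Pooled pair-stability counts are only meaningful on a shared gene
    universe, so cross-platform analyses should intersect first.
    """
    if not matrices:
        raise ValueError("no matrices given")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene sets have empty intersection")
    genes = sorted(common)
    logger.info("intersect_genes: %d common genes", len(genes))
    return [m.subset_genes(genes) for m in matrices]


def concat_samples(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Pool samples of matrices sharing one gene universe (column-wise concat)."""
    mats = intersect_genes(*matrices)
    data = pd.concat([m.data for m in mats], axis=1)
    batches = [
        m.batch if m.batch is not None else pd.Series(pd.NA, index=m.data.columns)
        for m in mats
    ]
    batch = pd.concat(batches)
    if batch.isna().all():
        batch = None
    return ExpressionMatrix(data, batch)
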