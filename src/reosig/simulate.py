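"""Synthetic multi-platform expression cohorts with planted reversal pairs.

The generator produces the statistical structure the discovery pipeline
assumes, so every downstream stage is testable without any download:

1. a latent log2-abundance per gene and sample = class template + Gaussian
   noise; planted pairs' templates are separated by ``delta_non`` in the
   non-cancer classes (gene_high below its partner) and by ``delta_gc`` in
   cancer (gene_high above), while background genes share one template
   across all classes;
2. exponentiation to the linear abundance scale;
3. cancer samples are convex purity mixtures p·tumor + (1−p)·normal taken
   in linear abundance space — bulk signal is a cell-proportion-weighted
   sum — with p the tumor epithelial proportion; adjacent-normal tissue is
   modelled as a low-purity mixture of the same kind;
4. a strictly increasing per-sample distortion with batch-specific
   parameters (power and affine maps composed) emulates platform and lab
   effects; it is applied after mixing, because measurement happens on the
   composite tissue, and by construction can never change a within-sample
   ordering.

With noise σ and planted separation δ, the per-sample probability that a
planted ordering flips is Φ(−δ/(σ√2)) — the difference of two latents is
Normal(δ, 2σ²) — which is how flip rates are calibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CLASSES, ClassLabels, ExpressionMatrix

__all__ = [
    "PlantedPair",
    "MonotoneDistortion",
    "CohortSpec",
    "SyntheticCohort",
    "TABLE1_PURITIES",
    "mix_purity",
    "monotone_distort",
    "simulate_cohort",
    "two_pair_study_spec",
]

#: Tumor epithelial cell proportions measured in the 21 surgical specimens
#: (seven patients, three tumor locations each); range 14-93%.
TABLE1_PURITIES = (
    0.23, 0.79, 0.53,
    0.53, 0.28, 0.89,
    0.27, 0.73, 0.93,
    0.35, 0.67, 0.89,
    0.88, 0.37, 0.14,
    0.88, 0.33, 0.57,
    0.15, 0.74, 0.47,
)


@dataclass(frozen=True)
class PlantedPair:
    """A planted reversal pair with latent log2 separations per group.

    In non-cancer classes the template of ``gene_high`` sits ``delta_non``
    below its partner's; in cancer it sits ``delta_gc`` above.  Both deltas
    must be positive.  ``base_log2`` optionally pins the partner gene's
    template (e.g. to place a pair among highly expressed genes); when None
    the partner's template is drawn like a background gene's.
    """

    gene_high: str
    gene_low: str
    delta_non: float = 1.5
    delta_gc: float = 1.5
    base_log2: float | None = None

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise ValueError("planted pair needs two distinct genes")
        if self.delta_non <= 0 or self.delta_gc <= 0:
            raise ValueError("planted separations must be positive")

    def gc_orientation_survives(self, p: float) -> bool:
        """Whether the cancer ordering survives a purity-p linear mixture.

        With partner abundance b, the mixture compares
        p·b·2^delta_gc + (1−p)·b·2^−delta_non against b, so survival is
        independent of b and monotone in p (zero noise).
        """
        return p * 2.0 ** self.delta_gc + (1 - p) * 2.0 ** -self.delta_non > 1.0


@dataclass(frozen=True)
class MonotoneDistortion:
    """x ↦ scale·x^power + offset on the positive reals.

    Strictly increasing by construction (scale > 0, power > 0, offset ≥ 0);
    non-monotone parameterisations are rejected at construction.
    """

    scale: float = 1.0
    power: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.power <= 0:
            raise ValueError(f"power must be positive, got {self.power}")
        if self.offset < 0:
            raise ValueError(f"offset must be nonnegative, got {self.offset}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(x, dtype=float) ** self.power + self.offset


def monotone_distort(sample: np.ndarray, params: MonotoneDistortion) -> np.ndarray:
    """Apply a strictly increasing distortion to one sample's abundances.

    Output within-sample orderings are identical to the input's.
    """
    sample = np.asarray(sample, dtype=float)
    if (sample < 0).any():
        raise ValueError("abundances must be nonnegative")
    return params(sample)


def mix_purity(tumor: np.ndarray, normal: np.ndarray, p: float) -> np.ndarray:
    """Convex combination p·tumor + (1−p)·normal in linear abundance space."""
    if not 0 < p <= 1:
        raise ValueError(f"purity must lie in (0, 1], got {p}")
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("tumor and normal vectors must have equal length")
    if (tumor < 0).any() or (normal < 0).any():
        raise ValueError("abundances must be nonnegative")
    return p * tumor + (1 - p) * normal


_DEFAULT_SIZES: Mapping[str, int] = {"NORMAL": 100, "GASTRITIS": 100, "GC": 100}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe a desk-scale study: 500 genes, 100 samples in each of
    the normal, gastritis and cancer classes, three platforms, log2 latent
    noise 0.2, full tumor purity.  ``class_sizes`` may add IM and GC_ADJ
    samples; adjacent-normal purity is drawn uniformly from
    ``adj_purity_range``.
    """

    n_genes: int = 500
    class_sizes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    planted_pairs: tuple[PlantedPair, ...] = ()
    noise_sd: float = 0.2
    purity_values: tuple[float, ...] = (1.0,)
    adj_purity_range: tuple[float, float] = (0.1, 0.3)
    n_batches: int = 3
    seed: int = 0
    template_loc: float = 6.0
    template_scale: float = 2.0

    def __post_init__(self) -> None:
        self.class_sizes = dict(self.class_sizes)
        self.planted_pairs = tuple(self.planted_pairs)
        bad = set(self.class_sizes) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown classes in class_sizes: {sorted(bad)}")
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be nonnegative")
        if self.n_genes < 2 * len(self.planted_pairs) or self.n_genes < 2:
            raise ValueError(
                f"n_genes={self.n_genes} cannot host {len(self.planted_pairs)} "
                "planted pairs (needs at least 2 genes per pair)"
            )
        genes = [g for p in self.planted_pairs for g in (p.gene_high, p.gene_low)]
        if len(set(genes)) != len(genes):
            raise ValueError("planted pairs must use disjoint genes")
        for p in self.purity_values:
            if not 0 < p <= 1:
                raise ValueError(f"purity values must lie in (0, 1], got {p}")
        lo, hi = self.adj_purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"invalid adj_purity_range {self.adj_purity_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be at least 1")


@dataclass
class SyntheticCohort:
    """A generated cohort: data, labels, and the planted ground truth."""

    matrix: ExpressionMatrix
    labels: ClassLabels
    truth: tuple[PlantedPair, ...]
    purity: pd.Series  # tumor proportion per GC / GC_ADJ sample

    def write(self, matrix_path, labels_path, truth_path) -> None:
        from .matrix import write_class_labels, write_expression_matrix

        write_expression_matrix(self.matrix, matrix_path)
        write_class_labels(self.labels, labels_path)
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "planted_pairs": [
                        {
                            "gene_high": p.gene_high,
                            "gene_low": p.gene_low,
                            "delta_non": p.delta_non,
                            "delta_gc": p.delta_gc,
                        }
                        for p in self.truth
                    ],
                    "purity": {k: float(v) for k, v in self.purity.items()},
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _gene_names(spec: CohortSpec) -> list[str]:
    planted = [g for p in spec.planted_pairs for g in (p.gene_high, p.gene_low)]
    n_bg = spec.n_genes - len(planted)
    width = len(str(spec.n_genes))
    background = [f"BG{i:0{width}d}" for i in range(1, n_bg + 1)]
    clash = set(planted) & set(background)
    if clash:
        raise ValueError(f"planted gene names collide with background names: {clash}")
    return planted + background


def _templates(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent log2 templates: (non-GC classes, GC tumor), aligned to genes.

    Background templates are resampled until they fall outside every planted
    pair's corridor (partner − delta_non, partner + delta_gc).  A background
    gene inside a corridor would genuinely reverse against the pair's moving
    gene — it sits between that gene's two class levels — so keeping
    corridors empty is what makes the planted pairs the complete set of
    reversals and gives them controlled rank gaps.
    """
    genes = _gene_names(spec)
    idx = {g: i for i, g in enumerate(genes)}
    base = rng.normal(spec.template_loc, spec.template_scale, size=len(genes))

    corridors = []
    for p in spec.planted_pairs:
        partner = base[idx[p.gene_low]] if p.base_log2 is None else p.base_log2
        base[idx[p.gene_low]] = partner
        corridors.append((partner - p.delta_non, partner + p.delta_gc))

    planted_idx = {
        idx[g] for p in spec.planted_pairs for g in (p.gene_high, p.gene_low)
    }
    background = np.array(
        [i for i in range(len(genes)) if i not in planted_idx], dtype=np.int64
    )
    for _ in range(1000):
        inside = np.zeros(len(background), dtype=bool)
        for lo, hi in corridors:
            inside |= (base[background] > lo) & (base[background] < hi)
        if not inside.any():
            break
        base[background[inside]] = rng.normal(
            spec.template_loc, spec.template_scale, size=int(inside.sum())
        )
    else:
        raise ValueError(
            "planted corridors cover too much of the template distribution; "
            "reduce the separations or move base_log2 toward the tails"
        )

    non = base.copy()
    gc = base.copy()
    for p in spec.planted_pairs:
        partner = base[idx[p.gene_low]]
        non[idx[p.gene_high]] = partner - p.delta_non
        gc[idx[p.gene_high]] = partner + p.delta_gc
    return non, gc


def _batch_distortions(
    n_batches: int, rng: np.random.Generator
) -> list[MonotoneDistortion]:
    out = []
    for _ in range(n_batches):
        out.append(
            MonotoneDistortion(
                scale=float(rng.lognormal(0.0, 0.5)),
                power=float(rng.uniform(0.6, 1.6)),
                offset=float(rng.uniform(0.0, 0.5)),
            )
        )
    return out


def simulate_cohort(spec: CohortSpec, sampling_seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort from a spec; reproducible for a fixed seed.

    Gene templates and batch distortion parameters derive from ``spec.seed``
    alone.  ``sampling_seed`` (default: the spec seed) controls per-sample
    noise and purity draws, so an independent validation cohort can share
    the same latent gene structure: same spec, different ``sampling_seed``.
    """
    rng_struct = np.random.default_rng(spec.seed)
    non_tpl, gc_tpl = _templates(spec, rng_struct)
    distortions = _batch_distortions(spec.n_batches, rng_struct)
    rng = np.random.default_rng(spec.seed if sampling_seed is None else sampling_seed)

    genes = _gene_names(spec)
    columns: dict[str, np.ndarray] = {}
    label_rows: dict[str, str] = {}
    purity_rows: dict[str, float] = {}

    def _latent(template: np.ndarray) -> np.ndarray:
        if spec.noise_sd == 0:
            return template
        return template + rng.normal(0.0, spec.noise_sd, size=template.shape)

    order = [c for c in CLASSES if spec.class_sizes.get(c, 0) > 0]
    for cls in order:
        n = spec.class_sizes[cls]
        for i in range(n):
            sid = f"{cls}_{i + 1:03d}"
            if cls in ("NORMAL", "GASTRITIS", "IM"):
                abundance = 2.0 ** _latent(non_tpl)
            else:
                if cls == "GC":
                    p = spec.purity_values[i % len(spec.purity_values)]
                else:  # GC_ADJ: low-purity mixture of the same tumor process
                    p = float(rng.uniform(*spec.adj_purity_range))
                tumor = 2.0 ** _latent(gc_tpl)
                normal = 2.0 ** _latent(non_tpl)
                abundance = mix_purity(tumor, normal, p)
                purity_rows[sid] = p
            columns[sid] = abundance
            label_rows[sid] = cls

    sample_ids = list(columns)
    batch_ids = [i % spec.n_batches for i in range(len(sample_ids))]
    data = pd.DataFrame(columns, index=genes)
    for sid, b in zip(sample_ids, batch_ids):
        data[sid] = monotone_distort(data[sid].to_numpy(), distortions[b])
    batch = pd.Series([f"batch{b + 1}" for b in batch_ids], index=sample_ids)

    return SyntheticCohort(
        matrix=ExpressionMatrix(data, batch),
        labels=ClassLabels(pd.Series(label_rows, name="class")),
        truth=spec.planted_pairs,
        purity=pd.Series(purity_rows, dtype=float),
    )


def two_pair_study_spec(
    seed: int = 0,
    noise_sd: float = 0.2,
    n_per_class: int = 100,
    n_genes: int = 500,
    low_purity: float = 0.14,
) -> CohortSpec:
    """The canonical two-pair discovery study.

    Two reversal pairs are planted among background genes, and one GC
    specimen per hundred is a low-purity mixture at the smallest tumor
    epithelial proportion measured in the surgical series (14%).  The pairs
    are deliberately asymmetric:

    * ``PAIR1HI``/``PAIR1LO`` sits in the dense centre of the template
      distribution, so noisy neighbours slip into its rank gap and give it
      the larger reversal degree — but its cancer ordering does not survive
      a 14%-purity mixture (p·2^1.1 + (1−p)·2^−2.2 < 1 at p = 0.14);
    * ``PAIR2HI``/``PAIR2LO`` sits among highly expressed genes in the
      sparse upper tail (small rank gap, smaller degree) and its stronger
      cancer separation tolerates 14% purity.

    The single top pair therefore misses the low-purity specimen while the
    two-pair majority vote classifies every training sample correctly —
    the reason a multi-pair signature beats the single best reversal pair.
    Noise-driven flips of every planted ordering stay well below 1% per
    sample (flip probability Φ(−δ/(σ√2)) for separation δ).
    """
    return CohortSpec(
        n_genes=n_genes,
        class_sizes={"NORMAL": n_per_class, "GASTRITIS": n_per_class, "GC": n_per_class},
        planted_pairs=(
            PlantedPair("PAIR1HI", "PAIR1LO", delta_non=2.2, delta_gc=1.1, base_log2=6.0),
            PlantedPair("PAIR2HI", "PAIR2LO", delta_non=1.2, delta_gc=3.4, base_log2=12.0),
        ),
        noise_sd=noise_sd,
        purity_values=(low_purity,) + (1.0,) * 99,
        n_batches=3,
        seed=seed,
    )
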