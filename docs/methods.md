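# Methods

## Model and assumptions

The classifier is purely ordinal.  For a pair of genes (i, j) the only
datum used is whether gene i's measured abundance strictly exceeds gene
j's within a sample.  The working assumptions are:

* measurement distortions act per sample and are strictly increasing on
  the positive reals (platform response curves, scaling, library size),
  so they never change a within-sample ordering;
* a gene pair that is *stable* (same ordering in ≥ 99% of a class's
  samples) in both the cancer and non-cancer populations, with opposite
  orientations, carries diagnostic signal for a single new sample;
* bulk tumor specimens are cell mixtures, so the observed abundance is a
  convex combination of tumor and non-tumor expression in linear space;
  an ordering survives impurity as long as the mixture does not cross.

All quantities are defined with strict inequalities.  Exact ties in
measured abundance (which produce tied average ranks) count toward
neither orientation when mining and contribute no vote when classifying —
the fail-safe reading of a strict-inequality definition.  How a real
within-pair tie should be scored is not observable from our sources; the
package exposes no alternative because any other choice weakens the
strictness guarantee.

## Discovery procedure

1. Rank genes within each sample (ascending, average ties; the direction
   is an internal convention — every downstream quantity uses either
   order comparisons or absolute rank differences, both direction-
   symmetric).
2. Mine stable pairs per class.  The threshold comparison is exact
   rational arithmetic: a float 0.99 is interpreted as 99/100 and the test
   is `count·den ≥ num·n` in integers.  At n = 23 samples, 99% therefore
   unambiguously requires all 23; at n = 100 it tolerates exactly one
   discordant sample.  This granularity is visible behaviour: a cohort
   with 100 cancer samples can carry one low-purity specimen that reverses
   a pair without destabilising it, while a 40-sample cohort cannot.
3. Intersect the normal and gastritis stable sets (identical orientation
   required; support recorded as the minimum) to form the non-GC
   consensus.  Consensus across classes — rather than mining on pooled
   non-GC samples — means a pair must be independently stable in each
   benign condition.
4. Reversal pairs: stable in both the consensus and the GC set with
   opposite orientations; reported in the GC orientation.
5. Score each reversal pair by the geometric mean of its class-wise mean
   absolute rank differences (`avgR_ij`), sort descending; ties broken
   lexicographically by (gene_high, gene_low) for determinism.
6. Sweep top-k signatures over the training samples with the vote rule
   and select the smallest k attaining maximal accuracy (parsimony).

Training uses the normal and gastritis classes against GC.
Intestinal-metaplasia samples may be present in a cohort but do not
define the consensus by default, and GC-adjacent samples never enter
training; at evaluation time GC-adjacent truth defaults to the GC side
(an adjacent-normal specimen called cancer is the desired behaviour for
mislocated biopsies) and can be switched.

## Classification and evaluation

A sample votes once per signature pair (strict GC-orientation check);
`at_least_half` labels GC when `2·votes ≥ k`, so the published k = 2
signature needs one concordant pair.  The stricter `all_pairs` rule is
available for sensitivity analysis.  Samples missing a signature gene
abstain and are excluded from metrics (reported separately).

The ROC score is the discrete fraction votes/k — with k = 2 only three
operating points exist.  The AUC is still well defined as the
tie-corrected Mann–Whitney probability; it is computed by midranks and is
identical (to 1e-12, verified against an explicit pairwise count) to the
trapezoidal area under the swept ROC curve.  The standard error uses the
Hanley–McNeil closed form with Q1 = A/(2−A), Q2 = 2A²/(1+A), and the 95%
interval A ± 1.96·SE is clipped to [0, 1] — which is how an interval like
"0.95–1" arises.  Display rounding is two decimals on percentages;
internal values are never rounded.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not a biological transcriptome.  Per gene, a latent log2 template is
drawn once (Normal with mean 6, SD 2 — a microarray-like dynamic range)
and shared across classes; per sample, Gaussian noise (default SD 0.2) is
added and the result exponentiated.  Planted pairs separate the moving
gene's template by `delta_non` below its partner in benign classes and
`delta_gc` above in cancer.  The per-sample probability that noise flips
a planted ordering has the closed form Φ(−δ/(σ√2)), which is used both to
calibrate defaults (all planted separations keep flips well under 1% per
sample) and as a generator correctness test at n = 2000.

Two structural choices matter:

* **Reserved corridors.**  Background templates are resampled until they
  fall outside every planted pair's interval (partner − delta_non,
  partner + delta_gc).  A background gene inside that corridor would sit
  between the moving gene's two class levels and therefore genuinely
  reverse against it — the planted pairs would not be the complete
  reversal set and "exact recovery" would be ill-posed.  Corridors also
  control rank gaps: a pair in the dense centre of the template
  distribution accumulates rank-difference mass from noisy neighbours
  slipping into its corridor, while a pair in the sparse upper tail keeps
  a rank gap near 1.  This is how the canonical study orders the two
  planted pairs by reversal degree deterministically.
* **Purity as part of the study conditions.**  Cancer samples are linear
  mixtures p·tumor + (1−p)·normal of independently drawn profiles, p
  taken from the spec's purity list (GC-adjacent samples are low-purity
  mixtures, p ~ U(0.1, 0.3), reflecting the premise that adjacent tissue
  acquires tumor-like signal).  In the canonical two-pair study one GC
  specimen per hundred is mixed at p = 0.14, the lowest tumor epithelial
  proportion in the measured series.  The two planted pairs are
  asymmetric by design: the large-degree pair's cancer ordering does not
  survive p = 0.14 (p·2^1.1 + (1−p)·2^−2.2 < 1), the small-degree pair's
  does (its cancer separation is 3.4 log2 units).  The top single pair
  therefore misses that specimen while the two-pair majority classifies
  every training sample — the mechanism by which the selection step
  prefers k = 2 over the more parsimonious k = 1, and a faithful
  miniature of why multi-pair voting beats the single best pair on
  heterogeneous tissue.

Batch effects are modelled as per-sample strictly increasing maps
x ↦ s·x^γ + o with batch-specific parameters (log-normal scale, power
U(0.6, 1.6), offset U(0, 0.5)), applied after mixing because measurement
happens on the composite tissue.  Non-monotone parameterisations are
rejected at construction, so distortions cannot change orderings by
construction; the invariance is nevertheless asserted bit-for-bit in
tests over random distortions.

What the generator does **not** emulate: correlated gene-gene noise,
count-based (negative binomial) sampling, RNA degradation, amplification
bias, missing values, or realistic pathway structure.  Passing tests
demonstrate the pipeline's algorithmic correctness and its invariances,
not clinical performance on real tissue.

## Problem sizes and numerical choices

Desk-scale defaults: 500 genes, 100 samples per class, 3 batches; an
all-pairs scan at that scale visits 124,750 pairs and a fitted study runs
in well under a second.  Mining is blocked (rows of 128 genes against the
full rank matrix) so memory stays bounded; a candidate-pair restriction
is available for larger universes.  The planted-recovery study uses 100
seeded replicates; the distortion-invariance study 100 random
distortions; the purity sweep the 21 measured proportions.  Cross-cohort
analyses must share a gene universe: `intersect_genes` restricts matrices
to their sorted common genes, and mining refuses mismatched universes
rather than silently reindexing.  Pooling samples across platforms needs
no normalisation because all statistics are within-sample.

Validation cohorts reuse a spec's seed-determined templates and batch
distortions while resampling noise and purity (`sampling_seed`), so
train/validation splits share latent gene structure the way two cohorts
profiled on the same genes do.

## Known limitations

* Signature selection is on training accuracy, by design — the procedure
  being reproduced selects on training data; no cross-validation is
  offered.
* Stability mining has no significance control (no FDR/permutation);
  with ~10⁵ stable pairs at desk scale, consensus counts are descriptive.
* The 99% threshold's integer granularity makes behaviour near the
  boundary sensitive to class size (one tolerated flip per 100 samples,
  none below); this is inherent to the definition, not an artifact.
* The generator's independence assumptions make recovery easier than on
  real data with correlated expression programs.
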