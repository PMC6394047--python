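"""Synthetic-cohort generator: determinism, planted structure, purity
mixtures, monotone distortions and the noise-flip closed form."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from reosig import (
    CohortSpec,
    MonotoneDistortion,
    PlantedPair,
    mix_purity,
    monotone_distort,
    rank_transform,
    simulate_cohort,
)
from reosig.simulate import two_pair_study_spec


def _support(matrix, labels, cls, gene_a, gene_b):
    """Fraction of class samples with gene_a strictly above gene_b."""
    samples = labels.samples_of(cls)
    sub = matrix.data.loc[[gene_a, gene_b], samples]
    return float((sub.iloc[0] > sub.iloc[1]).mean())


class TestMixPurity:
    def test_pure_tumor_is_identity(self):
        t = np.array([3.0, 1.0])
        assert np.array_equal(mix_purity(t, np.array([9.0, 9.0]), 1.0), t)

    def test_midpoint(self):
        out = mix_purity(np.array([10.0, 2.0]), np.array([2.0, 10.0]), 0.5)
        assert np.array_equal(out, np.array([6.0, 6.0]))

    def test_lowest_measured_purity_preserves_strong_tumor_ordering(self):
        # strongly tumor-high gene survives a 14% mixture
        out = mix_purity(np.array([100.0, 1.0]), np.array([1.0, 2.0]), 0.14)
        assert np.allclose(out, [14.86, 1.86])
        assert out[0] > out[1]

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_purity_outside_unit_interval_rejected(self, p):
        with pytest.raises(ValueError):
            mix_purity(np.ones(2), np.ones(2), p)


class TestMonotoneDistort:
    def test_identity_parameters(self):
        v = np.array([1.0, 4.0, 9.0])
        assert np.array_equal(monotone_distort(v, MonotoneDistortion()), v)

    def test_square_then_scale_preserves_order(self):
        v = np.array([1.0, 4.0, 9.0])
        out = monotone_distort(v, MonotoneDistortion(scale=3.0, power=2.0, offset=1.0))
        assert np.array_equal(np.argsort(out), np.argsort(v))

    @pytest.mark.parametrize(
        "kwargs", [{"scale": 0.0}, {"scale": -1.0}, {"power": 0.0}, {"offset": -0.5}]
    )
    def test_non_monotone_parameterisations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MonotoneDistortion(**kwargs)

    def test_random_distortions_never_change_ranks(self):
        """100 random draws: the rank matrix is bit-identical to undistorted."""
        rng = np.random.default_rng(11)
        from reosig import ExpressionMatrix

        df = pd.DataFrame(
            rng.lognormal(2, 1, size=(12, 6)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(6)],
        )
        base = rank_transform(ExpressionMatrix(df))
        for _ in range(100):
            d = MonotoneDistortion(
                scale=rng.uniform(0.1, 10),
                power=rng.uniform(0.3, 3),
                offset=rng.uniform(0, 5),
            )
            distorted = df.apply(lambda col: monotone_distort(col.to_numpy(), d))
            r = rank_transform(ExpressionMatrix(distorted))
            assert np.array_equal(base.ranks.to_numpy(), r.ranks.to_numpy())


class TestSimulateCohort:
    def test_zero_noise_full_purity_plants_exact_orderings(self):
        spec = CohortSpec(
            n_genes=40,
            class_sizes={"NORMAL": 10, "GASTRITIS": 10, "GC": 10},
            planted_pairs=(PlantedPair("HI", "LO", 1.0, 1.0),),
            noise_sd=0.0,
            purity_values=(1.0,),
            seed=3,
        )
        c = simulate_cohort(spec)
        for cls, expected in [("NORMAL", 0.0), ("GASTRITIS", 0.0), ("GC", 1.0)]:
            assert _support(c.matrix, c.labels, cls, "HI", "LO") == expected

    def test_same_seed_reproduces_different_seed_differs(self):
        spec = two_pair_study_spec(seed=5, n_genes=60, n_per_class=8)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.matrix.data, b.matrix.data)
        other = simulate_cohort(two_pair_study_spec(seed=6, n_genes=60, n_per_class=8))
        assert not a.matrix.data.equals(other.matrix.data)

    def test_sampling_seed_keeps_templates_but_resamples_noise(self):
        spec = two_pair_study_spec(seed=5, n_genes=60, n_per_class=8)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec, sampling_seed=777)
        assert not a.matrix.data.equals(b.matrix.data)
        # planted structure identical: same orientations in both cohorts
        for c in (a, b):
            assert _support(c.matrix, c.labels, "GC", "PAIR2HI", "PAIR2LO") == 1.0

    def test_all_abundances_positive_and_labels_cover(self):
        c = simulate_cohort(two_pair_study_spec(seed=1, n_genes=50, n_per_class=6))
        assert (c.matrix.data.to_numpy() > 0).all()
        assert set(c.labels.sample_ids) == set(c.matrix.sample_ids)
        assert len(set(c.matrix.batch)) == 3

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(
                n_genes=3,
                planted_pairs=(
                    PlantedPair("a", "b"), PlantedPair("c", "d"),
                ),
            )

    def test_noise_flip_fraction_matches_gaussian_closed_form(self):
        """Planted-order violations occur at rate Φ(−δ/(σ√2)).

        The latent difference of the two genes is Normal(δ, 2σ²), so the
        violation probability has a closed form; the observed fraction over
        2000 samples must fall within 3 Monte-Carlo standard errors.
        """
        delta, sigma, n = 0.5, 0.4, 2000
        spec = CohortSpec(
            n_genes=10,
            class_sizes={"NORMAL": n},
            planted_pairs=(PlantedPair("HI", "LO", delta_non=delta, delta_gc=1.0),),
            noise_sd=sigma,
            seed=17,
        )
        c = simulate_cohort(spec)
        # planted non-GC orientation is LO > HI; violation = HI >= LO
        violations = 1.0 - _support(c.matrix, c.labels, "NORMAL", "LO", "HI")
        expected = scipy.stats.norm.cdf(-delta / (sigma * np.sqrt(2)))
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(violations - expected) <= 3 * mc_se

    def test_purity_monotonicity_of_planted_orientation(self):
        """Zero-noise mixtures cross zero at most once: if the tumor ordering
        holds at p0 it holds for every p ≥ p0."""
        pair = PlantedPair("HI", "LO", delta_non=1.2, delta_gc=3.4)
        grid = np.linspace(0.01, 1.0, 100)
        survives = np.array([pair.gc_orientation_survives(p) for p in grid])
        first = np.argmax(survives)
        assert survives[first:].all()
        # direct mixture arithmetic agrees with the helper
        for p in (0.05, 0.14, 0.5):
            mixed = mix_purity(
                np.array([2.0**3.4, 1.0]), np.array([2.0**-1.2, 1.0]), p
            )
            assert (mixed[0] > mixed[1]) == pair.gc_orientation_survives(p)

    def test_gc_adj_low_purity_recorded(self):
        spec = CohortSpec(
            n_genes=20,
            class_sizes={"NORMAL": 4, "GASTRITIS": 4, "GC": 4, "GC_ADJ": 6},
            planted_pairs=(PlantedPair("HI", "LO"),),
            noise_sd=0.1,
            adj_purity_range=(0.1, 0.3),
            seed=9,
        )
        c = simulate_cohort(spec)
        adj = c.labels.samples_of("GC_ADJ")
        assert set(adj) <= set(c.purity.index)
        assert ((c.purity[adj] >= 0.1) & (c.purity[adj] <= 0.3)).all()
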