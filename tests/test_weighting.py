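"""Distance metrics, segregation filters and sampling probabilities."""

import numpy as np
import pytest

from transqtl.genotypes import GenotypeMatrix
from transqtl.pheno_sim import PhenotypeVector, simulate_phenotype
from transqtl.weighting import (
    DistanceContext,
    HybridSampleWeighter,
    gower_distance,
    jaccard_distance,
    mean_distance,
    pairwise_distances,
    resample_training_set,
    sampling_probabilities,
    segregating_samples,
    top_wild_markers,
)

from _oracles import gower_loop, jaccard_loop
from conftest import make_pheno


def _geno(dosage, population="hybrid"):
    dosage = np.asarray(dosage)
    return GenotypeMatrix(
        [f"s{i}" for i in range(dosage.shape[0])],
        [f"m{j}" for j in range(dosage.shape[1])],
        dosage,
        population,
    )


class TestTopWildMarkers:
    def test_marker_equal_to_phenotype_ranks_first(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(40, 5))
        G = _geno(dosage, "wild")
        pheno = make_pheno(G.sample_ids, dosage[:, 3].astype(float))
        assert top_wild_markers(G, pheno, 1)[0] == "m3"

    def test_cutoff_equal_to_all_markers(self):
        rng = np.random.default_rng(1)
        G = _geno(rng.integers(0, 3, size=(30, 4)), "wild")
        pheno = make_pheno(G.sample_ids, rng.normal(size=30))
        assert sorted(top_wild_markers(G, pheno, 4)) == ["m0", "m1", "m2", "m3"]

    def test_ordering_by_absolute_correlation(self):
        # 6-sample toy table with |r| approximately 1.0 / 0.65 / 0.05
        g = np.array(
            [[0, 0, 1], [1, 0, 0], [1, 1, 2], [2, 2, 0], [2, 2, 1], [0, 1, 2]]
        )
        y = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 0.0])  # equals m0
        G = _geno(g, "wild")
        pheno = make_pheno(G.sample_ids, y)
        top2 = top_wild_markers(G, pheno, 2)
        assert top2 == ["m0", "m1"]

    def test_zero_variance_phenotype_rejected(self):
        G = _geno(np.zeros((5, 2), dtype=int), "wild")
        with pytest.raises(ValueError, match="variance"):
            top_wild_markers(G, make_pheno(G.sample_ids, np.ones(5)), 1)


class TestSegregatingSamples:
    def test_extreme_tails_on_1_to_20(self):
        pheno = make_pheno([f"s{v}" for v in range(1, 21)], np.arange(1.0, 21.0))
        assert segregating_samples(pheno, 0.05) == {"s1", "s20"}

    def test_near_half_quantile_keeps_all(self):
        pheno = make_pheno([f"s{v}" for v in range(10)], np.arange(10.0))
        assert len(segregating_samples(pheno, 0.4999)) == 10

    def test_single_tail_modes(self):
        pheno = make_pheno([f"s{v}" for v in range(1, 21)], np.arange(1.0, 21.0))
        assert segregating_samples(pheno, 0.05, "lower") == {"s1"}
        assert segregating_samples(pheno, 0.05, "upper") == {"s20"}

    def test_constant_phenotype_rejected(self):
        pheno = make_pheno(["a", "b"], [1.0, 1.0])
        with pytest.raises(ValueError, match="segregation"):
            segregating_samples(pheno, 0.1)

    def test_quantile_domain_enforced(self):
        pheno = make_pheno(["a", "b", "c"], [1.0, 2.0, 3.0])
        for q in (0.0, 0.5, 0.7):
            with pytest.raises(ValueError, match="quantile"):
                segregating_samples(pheno, q)


class TestGowerDistance:
    def test_hand_evaluations(self):
        ctx = DistanceContext(["a", "b"], [2.0, 2.0])
        assert gower_distance(np.array([0, 2]), np.array([0, 2]), ctx) == 0.0
        assert gower_distance(np.array([0, 2]), np.array([2, 2]), ctx) == pytest.approx(0.5)
        ctx1 = DistanceContext(["a"], [2.0])
        assert gower_distance(np.array([0]), np.array([2]), ctx1) == 1.0

    def test_invalid_markers_excluded(self):
        # second marker invalid (zero range): only the first contributes
        ctx = DistanceContext(["a", "b"], [2.0, 0.0])
        d = gower_distance(np.array([0, 1]), np.array([1, 1]), ctx)
        assert d == pytest.approx(0.5)
        with pytest.raises(ValueError, match="valid"):
            gower_distance(np.array([0]), np.array([1]), DistanceContext(["a"], [0.0]))


class TestJaccardDistance:
    def test_hand_evaluations(self):
        assert jaccard_distance(np.array([1, 0, 2]), np.array([1, 0, 2])) == 0.0
        assert jaccard_distance(np.array([1, 0, 2]), np.array([1, 1, 0])) == pytest.approx(2 / 3)
        assert jaccard_distance(np.array([1, 1, 0]), np.array([0, 0, 2])) == 1.0

    def test_all_zero_pair_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            jaccard_distance(np.zeros(3), np.zeros(3))


class TestMetricProperties:
    def test_agreement_with_bruteforce_loops(self):
        rng = np.random.default_rng(7)
        ctx = DistanceContext([f"m{j}" for j in range(10)], np.full(10, 2.0))
        for _ in range(1000):
            xi = rng.integers(0, 3, 10)
            xj = rng.integers(0, 3, 10)
            assert abs(gower_distance(xi, xj, ctx) - gower_loop(xi, xj, ctx.ranges)) < 1e-12
            if (xi != 0).any() or (xj != 0).any():
                assert abs(jaccard_distance(xi, xj) - jaccard_loop(xi, xj)) < 1e-12

    def test_symmetry_range_and_identity(self):
        rng = np.random.default_rng(8)
        ctx = DistanceContext([f"m{j}" for j in range(10)], np.full(10, 2.0))
        for _ in range(200):
            xi, xj = rng.integers(0, 3, (2, 10))
            for d in (
                lambda a, b: gower_distance(a, b, ctx),
                jaccard_distance,
            ):
                if d is jaccard_distance and not ((xi != 0).any() or (xj != 0).any()):
                    continue
                assert d(xi, xj) == pytest.approx(d(xj, xi))
                assert 0.0 <= d(xi, xj) <= 1.0
            if (xi != 0).any():
                assert jaccard_distance(xi, xi) == 0.0
            assert gower_distance(xi, xi, ctx) == 0.0

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        A = rng.integers(0, 3, (6, 8))
        B = rng.integers(1, 3, (4, 8))
        ctx = DistanceContext([f"m{j}" for j in range(8)], np.full(8, 2.0))
        for metric, scalar in (
            ("gower", lambda a, b: gower_distance(a, b, ctx)),
            ("jaccard", jaccard_distance),
        ):
            D = pairwise_distances(A, B, ctx, metric)
            for i in range(6):
                for j in range(4):
                    assert D[i, j] == pytest.approx(scalar(A[i], B[j]))


class TestMeanDistance:
    def test_reference_cases(self):
        ctx = DistanceContext(["a"], [2.0])
        x = np.array([0])
        refs = np.array([[0], [2]])
        assert mean_distance(x, refs[:1], ctx) == 0.0
        assert mean_distance(x, refs, ctx) == pytest.approx(0.5)  # mean of 0 and 1


class TestSamplingProbabilities:
    def test_hand_normalization(self):
        w = sampling_probabilities([0.2, 0.4, 0.8], [True, True, True])
        assert np.allclose(w.probabilities, [0.5, 0.375, 0.125])

    def test_equal_distances_uniform(self):
        w = sampling_probabilities([0.3, 0.3, 0.3, 0.3], [True] * 4)
        assert np.allclose(w.probabilities, 0.25)

    def test_unfiltered_baseline_rule(self):
        w = sampling_probabilities([0.0, 0.9], [True, False])
        assert np.allclose(w.probabilities, [0.5, 0.5])

    def test_exclude_unfiltered_strict_mode(self):
        w = sampling_probabilities([0.0, 0.9], [True, False], exclude_unfiltered=True)
        assert np.allclose(w.probabilities, [1.0, 0.0])

    def test_monotone_in_mean_distance(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            d = rng.uniform(0, 1, 20)
            flags = rng.random(20) < 0.7
            if not flags.any():
                continue
            w = sampling_probabilities(d, flags)
            df, pf = d[flags], w.probabilities[flags]
            order = np.argsort(df)
            assert (np.diff(pf[order]) <= 1e-12).all()
            assert w.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_weights_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = sampling_probabilities([1.0, 1.0], [True, True])
        assert np.allclose(w.probabilities, 0.5)


class TestResampleTrainingSet:
    def _data(self, n=10):
        rng = np.random.default_rng(11)
        G = _geno(rng.integers(0, 3, (n, 3)))
        pheno = make_pheno(G.sample_ids, np.arange(float(n)))
        return G, pheno

    def _weights(self, G, probs):
        from transqtl.weighting import SampleWeights

        n = len(probs)
        return SampleWeights(
            G.sample_ids, np.asarray(probs, float), np.zeros(n), np.ones(n, bool)
        )

    def test_point_mass_draws_one_sample(self):
        G, pheno = self._data(4)
        w = self._weights(G, [1.0, 0.0, 0.0, 0.0])
        G2, p2 = resample_training_set(G, pheno, w, seed=0)
        assert (G2.dosage == G.dosage[0]).all()
        assert (p2.values == pheno.values[0]).all()

    def test_rows_stay_paired(self):
        G, pheno = self._data(10)
        w = self._weights(G, np.full(10, 0.1))
        G2, p2 = resample_training_set(G, pheno, w, n_out=50, seed=1)
        # phenotype value encodes the original row index
        for k, v in enumerate(p2.values):
            assert (G2.dosage[k] == G.dosage[int(v)]).all()

    def test_uniform_draw_frequencies(self):
        G, pheno = self._data(10)
        w = self._weights(G, np.full(10, 0.1))
        _, p2 = resample_training_set(G, pheno, w, n_out=20000, seed=2)
        freqs = np.bincount(p2.values.astype(int), minlength=10) / 20000
        se = np.sqrt(0.1 * 0.9 / 20000)
        assert (np.abs(freqs - 0.1) < 3.5 * se).all()

    def test_seed_determinism(self):
        G, pheno = self._data(8)
        w = self._weights(G, np.full(8, 0.125))
        a = resample_training_set(G, pheno, w, seed=3)[1].values
        b = resample_training_set(G, pheno, w, seed=3)[1].values
        assert np.array_equal(a, b)


class TestHybridSampleWeighter:
    def test_consistent_hybrid_samples_get_high_probability(self):
        # wild panel: causal marker m0 drives the trait; hybrid samples whose
        # m0 genotype matches the wild phenotypic extremes should be drawn
        # preferentially
        rng = np.random.default_rng(12)
        n_w, n_h, m = 100, 80, 12
        wild = _geno(rng.integers(0, 3, (n_w, m)), "wild")
        wp = simulate_phenotype(wild, "m0", target_ve=0.9, seed=13)
        hyb = _geno(rng.integers(0, 3, (n_h, m)))
        hp = simulate_phenotype(hyb, "m0", target_ve=0.9, seed=14)
        est = HybridSampleWeighter(
            metric="gower", top_marker_cutoff=5, wild_seg_quantile=0.15,
            hybrid_seg_quantile=0.15,
        ).fit(wild, wp, hyb, hp)
        w = est.weights_
        assert "m0" in est.top_markers_
        assert w.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        # filtered extreme-dosage hybrids should beat the baseline weight
        extremes = np.isin(hyb.dosage[:, 0], [0, 2]) & w.filtered_flag
        assert w.probabilities[extremes].mean() > w.probabilities.mean()

    def test_sklearn_params_round_trip(self):
        est = HybridSampleWeighter(metric="jaccard", top_marker_cutoff=15)
        params = est.get_params()
        assert params["metric"] == "jaccard"
        est.set_params(metric="gower")
        assert est.metric == "gower"
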