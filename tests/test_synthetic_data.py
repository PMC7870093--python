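"""Generators: determinism, marginal laws, correlation imposition, benchmark."""

import numpy as np
import pytest

from neighbordist import (
    build_stack,
    estimate_maf,
    gaussian_to_binomial,
    gen_continuous,
    gen_feature_selection_benchmark,
    gen_fmri_stack,
    gen_gwas,
    impose_correlation,
    mean_abs_correlation,
    random_structured_correlation,
)
from neighbordist.gwas_moments import expected_gammas


class TestDeterminism:
    def test_generators_reproducible(self):
        a = gen_continuous(10, 5, "normal", seed=3).values
        b = gen_continuous(10, 5, "normal", seed=3).values
        np.testing.assert_array_equal(a, b)
        g1, g2 = (gen_gwas(10, 8, seed=3) for _ in range(2))
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
        np.testing.assert_array_equal(g1.encoding, g2.encoding)
        s1, s2 = (gen_fmri_stack(4, 5, seed=3) for _ in range(2))
        np.testing.assert_array_equal(s1.values, s2.values)
        assert gen_continuous(10, 5, seed=4).values[0, 0] != a[0, 0]


class TestContinuous:
    def test_normal_marginals(self):
        X = gen_continuous(10**4, 5, "normal", seed=0)
        assert np.allclose(X.values.mean(axis=0), 0.0, atol=0.05)
        assert np.allclose(X.values.var(axis=0), 1.0, atol=0.07)

    def test_uniform_support(self):
        X = gen_continuous(500, 20, "uniform", seed=1)
        assert (X.values >= 0).all() and (X.values < 1).all()


class TestGwas:
    def test_maf_recovery(self):
        G = gen_gwas(4000, 300, 0.1, 0.4, seed=6)
        fbar_hat = estimate_maf(G).mean()
        assert fbar_hat == pytest.approx(0.25, abs=0.02)

    def test_encoding_fraction(self):
        G = gen_gwas(5, 6000, eta=2.0, seed=9)
        frac_pupy = np.mean(G.encoding == "PuPy")
        assert frac_pupy == pytest.approx(1 / 3, abs=0.03)

    def test_genotype_support(self):
        G = gen_gwas(50, 40, seed=2)
        assert set(np.unique(G.genotypes)) <= {0, 1, 2}

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            gen_gwas(10, 10, 0.5, 0.1)


class TestStack:
    def test_layout_invariants(self):
        S = gen_fmri_stack(6, 5, seed=12)
        assert S.values.shape == (20, 6)
        np.testing.assert_allclose(S.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(S.values.std(axis=0), 1.0, atol=1e-12)

    def test_each_pair_twice(self):
        """Each unordered ROI pair appears in exactly two block rows per column."""
        p = 4
        mats = np.empty((2, p, p))
        r = np.random.default_rng(0)
        for i in range(2):
            A = r.uniform(-0.5, 0.5, size=(p, p))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            mats[i] = A
        S = build_stack(mats, standardize=False)
        col = S.values[:, 0]
        # sorted multiset of block entries == each upper-triangle z twice
        z = np.arctanh(mats[0][np.triu_indices(p, 1)])
        np.testing.assert_allclose(np.sort(col), np.sort(np.repeat(z, 2)), atol=1e-12)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            build_stack(np.zeros((3, 4, 5)))


class TestCorrelationTarget:
    def test_empty_graph_identity(self):
        R = random_structured_correlation(6, 0.0, hi=0.9, lo=0.0, seed=0)
        np.testing.assert_allclose(R.matrix, np.eye(6), atol=1e-12)

    def test_positive_definite(self):
        for prob in (0.05, 0.3, 0.9):
            R = random_structured_correlation(25, prob, hi=0.8, lo=0.1, seed=1)
            assert np.linalg.eigvalsh(R.matrix).min() > 0
            np.testing.assert_allclose(np.diag(R.matrix), 1.0, atol=1e-12)

    def test_complete_graph_high_correlation(self):
        R = random_structured_correlation(10, 1.0, hi=0.7, lo=0.0, seed=2)
        off = R.matrix[np.triu_indices(10, 1)]
        assert np.allclose(off, 0.7, atol=0.05)


class TestImposeCorrelation:
    def test_identity_target_is_noop(self, rng):
        X = gen_continuous(50, 6, seed=5)
        out = impose_correlation(X, np.eye(6))
        np.testing.assert_allclose(out.values, X.values, atol=1e-12)

    def test_two_attribute_target(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        X = gen_continuous(10**5, 2, seed=8)
        out = impose_correlation(X, R)
        r = np.corrcoef(out.values, rowvar=False)[0, 1]
        assert r == pytest.approx(0.6, abs=0.01)

    def test_rbar_tracks_target(self):
        target = random_structured_correlation(20, 0.4, hi=0.7, lo=0.0, seed=3)
        target_rbar = np.abs(target.matrix[np.triu_indices(20, 1)]).mean()
        X = impose_correlation(gen_continuous(20000, 20, seed=4), target)
        assert mean_abs_correlation(X) == pytest.approx(target_rbar, abs=0.03)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            impose_correlation(gen_continuous(10, 3, seed=0), np.eye(4))


class TestGaussianToBinomial:
    def test_extreme_inputs_map_to_extreme_genotypes(self):
        X = np.array([[-10.0, 10.0], [10.0, -10.0]])
        G = gaussian_to_binomial(X, np.array([0.3, 0.5]))
        np.testing.assert_array_equal(G.genotypes, [[0, 2], [2, 0]])

    def test_uncorrelated_marginals(self):
        X = gen_continuous(3 * 10**4, 2, seed=10)
        G = gaussian_to_binomial(X, np.array([0.5, 0.2]))
        freqs = np.bincount(G.genotypes[:, 0], minlength=3) / G.m
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)
        assert G.genotypes[:, 1].mean() == pytest.approx(2 * 0.2, abs=0.01)

    def test_encodings_attached_when_model_given(self):
        X = gen_continuous(100, 50, seed=11)
        G = gaussian_to_binomial(X, np.full(50, 0.3), expected_gammas(2.0), seed=0)
        assert G.encoding is not None and len(G.encoding) == 50


class TestMeanAbsCorrelation:
    def test_duplicated_attribute(self):
        col = np.random.default_rng(0).standard_normal(200)
        assert mean_abs_correlation(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_null_level(self):
        X = gen_continuous(10**4, 10, seed=13)
        assert mean_abs_correlation(X) < 0.02

    def test_sign_flip_invariance(self):
        X = gen_continuous(200, 6, seed=14).values
        flipped = X * np.array([1, -1, 1, -1, 1, -1])
        assert mean_abs_correlation(X) == pytest.approx(
            mean_abs_correlation(flipped), abs=1e-12
        )


class TestBenchmark:
    def test_balanced_classes_and_mask(self):
        X, y, mask = gen_feature_selection_benchmark(100, 1000, 100, seed=0)
        assert (y == 0).sum() == (y == 1).sum() == 50
        assert mask.sum() == 100 and X.values.shape == (100, 1000)

    def test_main_effects_separate(self):
        X, y, mask = gen_feature_selection_benchmark(
            200, 100, 20, effect="main", seed=1, main_shift=1.5
        )
        tstats = np.abs(
            X.values[y == 1].mean(0) - X.values[y == 0].mean(0)
        ) / X.values.std(0)
        assert np.median(tstats[mask]) > np.percentile(tstats[~mask], 95)

    def test_interaction_effects_differential_correlation(self):
        X, y, mask = gen_feature_selection_benchmark(
            400, 50, 20, effect="interaction", seed=2, interaction_corr=0.7
        )
        idx = np.flatnonzero(mask)
        sub1 = X.values[np.ix_(y == 1, idx)]
        sub0 = X.values[np.ix_(y == 0, idx)]
        r1 = np.abs(np.corrcoef(sub1, rowvar=False)[np.triu_indices(20, 1)]).mean()
        r0 = np.abs(np.corrcoef(sub0, rowvar=False)[np.triu_indices(20, 1)]).mean()
        assert r1 - r0 > 0.3
        # near-zero marginal mean difference for interaction attributes
        shift = np.abs(sub1.mean(0) - sub0.mean(0))
        assert shift.max() < 0.35

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError):
            gen_feature_selection_benchmark(99, 100, 10)
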