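"""Distance metrics: worked examples, brute-force oracles, metric axioms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import squareform

from neighbordist import (
    ContinuousMatrix,
    CorrelationStack,
    GenotypeData,
    attribute_diff,
    fmri_distance_matrix,
    fmri_roi_diff,
    gwas_diff,
    gwas_distance_matrix,
    lq_distance_matrix,
    roi_block_indices,
)
from neighbordist.synthetic_data import gen_fmri_stack, gen_gwas


def brute_force_lq(values, q, normalized=False):
    """Independent double-loop recomputation of the L_q distance matrix."""
    vals = np.array(values, dtype=float)
    if normalized:
        vals = vals / (vals.max(0) - vals.min(0))
    m = vals.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = np.sum(np.abs(vals[i] - vals[j]) ** q) ** (1.0 / q)
    return out


class TestLqDistance:
    def test_hand_examples(self):
        D = lq_distance_matrix(np.array([[0.0, 0.0], [1.0, 1.0]]), q=1)
        assert D.values[0, 1] == pytest.approx(2.0)
        # identical rows at any q
        X = np.array([[0.3, -1.2, 4.0], [0.3, -1.2, 4.0], [1.0, 0.0, 0.0]])
        for q in (1, 2, 3):
            assert lq_distance_matrix(X, q).values[0, 1] == 0.0

    @pytest.mark.parametrize("q", [1, 2, 3])
    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_brute_force(self, rng, q, normalized):
        X = rng.standard_normal((6, 5))
        D = lq_distance_matrix(X, q=q, normalized=normalized)
        np.testing.assert_allclose(
            D.values, brute_force_lq(X, q, normalized), atol=1e-12
        )

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_triangle_inequality(self, rng, q):
        X = rng.standard_normal((8, 4))
        for normalized in (False, True):
            D = lq_distance_matrix(X, q=q, normalized=normalized).values
            for i, j, k in itertools.permutations(range(8), 3):
                assert D[i, k] <= D[i, j] + D[j, k] + 1e-12

    def test_attribute_permutation_invariance(self, rng):
        X = rng.standard_normal((7, 6))
        perm = rng.permutation(6)
        for q in (1, 2):
            a = lq_distance_matrix(X, q).values
            b = lq_distance_matrix(X[:, perm], q).values
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_attribute_policy(self, rng):
        X = rng.standard_normal((5, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="zero range"):
            lq_distance_matrix(X, q=1, normalized=True)
        with pytest.warns(UserWarning, match="dropping"):
            D = lq_distance_matrix(X, q=1, normalized=True, on_degenerate="drop")
        expected = brute_force_lq(X[:, [0, 2]], 1, normalized=True)
        np.testing.assert_allclose(D.values, expected, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            lq_distance_matrix(np.array([[0.0, np.nan], [1.0, 2.0]]), q=1)


class TestAttributeDiff:
    def test_hand_examples(self):
        X = np.array([[0.0], [1.0], [3.0]])
        np.testing.assert_allclose(attribute_diff(X, 0), [1.0, 3.0, 2.0])
        np.testing.assert_allclose(
            attribute_diff(X, 0, normalized=True), [1 / 3, 1.0, 2 / 3]
        )

    def test_l1_is_sum_of_diffs(self, rng):
        X = rng.standard_normal((6, 4))
        total = sum(attribute_diff(X, a) for a in range(4))
        np.testing.assert_allclose(
            total, lq_distance_matrix(X, q=1).condensed(), atol=1e-12
        )

    def test_normalized_in_unit_interval(self, rng):
        X = rng.standard_normal((10, 3))
        d = attribute_diff(X, 2, normalized=True)
        assert (d >= 0).all() and (d <= 1).all()


class TestGwasDiff:
    @pytest.mark.parametrize(
        "gi,gj,metric,enc,expected",
        [
            (0, 2, "titv", "PuPy", 1.0),
            (1, 2, "titv", "PuPu", 0.25),
            (1, 2, "titv", "PyPy", 0.25),
            (0, 1, "titv", "PuPy", 0.5),
            (0, 2, "titv", "PuPu", 0.75),
            (2, 2, "titv", "PuPy", 0.0),
            (2, 2, "gm", None, 0.0),
            (2, 2, "am", None, 0.0),
            (0, 2, "am", None, 1.0),
            (1, 2, "am", None, 0.5),
            (0, 1, "gm", None, 1.0),
        ],
    )
    def test_diff_table(self, gi, gj, metric, enc, expected):
        assert gwas_diff(gi, gj, metric, enc) == expected
        assert gwas_diff(gj, gi, metric, enc) == expected  # symmetry

    def test_supports(self):
        encs = ("PuPu", "PuPy", "PyPy")
        gm = {gwas_diff(i, j, "gm") for i in range(3) for j in range(3)}
        am = {gwas_diff(i, j, "am") for i in range(3) for j in range(3)}
        titv = {
            gwas_diff(i, j, "titv", e)
            for i in range(3) for j in range(3) for e in encs
        }
        assert gm == {0.0, 1.0}
        assert am == {0.0, 0.5, 1.0}
        assert titv == {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_errors(self):
        with pytest.raises(ValueError):
            gwas_diff(3, 0, "gm")
        with pytest.raises(ValueError, match="encoding"):
            gwas_diff(0, 1, "titv")


class TestGwasDistanceMatrix:
    def test_identical_and_hand_examples(self):
        same = GenotypeData(np.ones((4, 5), dtype=int))
        assert gwas_distance_matrix(same, "gm").values.sum() == 0.0
        G = GenotypeData(np.array([[0, 1], [2, 2]]))
        assert gwas_distance_matrix(G, "gm").values[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("metric", ["gm", "am", "titv"])
    def test_matches_per_locus_loop(self, rng, metric):
        G = gen_gwas(8, 20, seed=99)
        D = gwas_distance_matrix(G, metric)
        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = sum(
                    gwas_diff(
                        int(G.genotypes[i, a]), int(G.genotypes[j, a]),
                        metric, G.encoding[a],
                    )
                    for a in range(20)
                )
        np.testing.assert_allclose(D.values, expected, atol=1e-12)

    def test_titv_requires_encoding(self):
        G = GenotypeData(np.array([[0, 1], [2, 2]]))
        with pytest.raises(ValueError, match="encoding"):
            gwas_distance_matrix(G, "titv")


class TestStackMetric:
    def test_block_indices(self):
        assert roi_block_indices(1, 10) == (1, 9)
        assert roi_block_indices(10, 10) == (82, 90)
        for p in (2, 3, 5, 8):
            covered = []
            for k in range(1, p + 1):
                s, e = roi_block_indices(k, p)
                covered.extend(range(s, e + 1))
            assert covered == list(range(1, p * (p - 1) + 1))
        with pytest.raises(IndexError):
            roi_block_indices(0, 10)
        with pytest.raises(IndexError):
            roi_block_indices(11, 10)

    def test_roi_diff_hand_example(self):
        # p=3: ROI 1's block holds its correlations with ROIs 2 and 3
        values = np.zeros((6, 2))
        values[0:2, 0] = [0.1, 0.2]
        values[0:2, 1] = [0.4, 0.0]
        S = CorrelationStack(values, p=3, standardized=False)
        assert fmri_roi_diff(S, 0, 1, 0) == pytest.approx(0.5)
        assert fmri_roi_diff(S, 0, 0, 0) == 0.0

    def test_roi_diffs_double_count_pairs(self, rng):
        S = gen_fmri_stack(4, 5, seed=3)
        total = sum(fmri_roi_diff(S, 0, 1, a) for a in range(5))
        # each unordered ROI pair appears in exactly two blocks
        assert total == pytest.approx(
            fmri_distance_matrix(S).values[0, 1], rel=1e-12
        )

    def test_distance_equals_l1_on_columns(self, rng):
        S = gen_fmri_stack(6, 4, seed=11)
        D = fmri_distance_matrix(S)
        L1 = lq_distance_matrix(ContinuousMatrix(S.values.T), q=1)
        np.testing.assert_allclose(D.values, L1.values, atol=1e-12)

    def test_identical_columns_zero(self):
        col = np.linspace(-1, 1, 6)
        S = CorrelationStack(np.column_stack([col, col]), p=3, standardized=False)
        assert fmri_distance_matrix(S).values.sum() == 0.0

    def test_normalized_block_scaling(self, rng):
        S = gen_fmri_stack(5, 4, seed=21)
        D = fmri_distance_matrix(S, normalized=True)
        scaled = S.values.copy()
        for a in range(4):
            block = slice(a * 3, (a + 1) * 3)
            scaled[block] /= scaled[block].max() - scaled[block].min()
        expected = brute_force_lq(scaled.T, 1)
        np.testing.assert_allclose(D.values, expected, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    m=st.integers(3, 7),
    p=st.integers(1, 5),
    q=st.integers(1, 3),
    seed=st.integers(0, 2**16),
)
def test_distance_matrix_axioms(m, p, q, seed):
    """Symmetry, zero diagonal, nonnegativity on random inputs."""
    X = np.random.default_rng(seed).standard_normal((m, p))
    D = lq_distance_matrix(X, q=q).values
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert (D >= 0).all()
    assert squareform(D, checks=False).shape == (m * (m - 1) // 2,)
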