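"""Scaling, extraction, non-negative rotation and contributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fannc import (
    ConcentrationMatrix, FactorSolution, average_scale, contributions,
    fit_fannc, nnc_rotate, normalize_profiles, reconstruct,
    unrotated_factor_model,
)
from fannc.core import ScaledMatrix

positive_matrices = arrays(
    np.float64, st.tuples(st.integers(2, 8), st.integers(2, 8)),
    elements=st.floats(0.1, 1e4),
)


class TestAverageScale:
    def test_row_arithmetic(self):
        cm = ConcentrationMatrix(np.array([[2.0, 4.0, 6.0], [5.0, 5.0, 5.0]]),
                                 ("A", "B"), ("s1", "s2", "s3"))
        sm = average_scale(cm)
        np.testing.assert_allclose(sm.values[0], [0.5, 1.0, 1.5])
        np.testing.assert_allclose(sm.values[1], [1.0, 1.0, 1.0])
        assert sm.row_means[0] == 4.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_matrices)
    def test_back_scaling_is_identity(self, vals):
        cm = ConcentrationMatrix(vals, tuple(f"c{i}" for i in range(vals.shape[0])),
                                 tuple(f"s{j}" for j in range(vals.shape[1])))
        sm = average_scale(cm)
        np.testing.assert_allclose(sm.values * sm.row_means[:, None], vals,
                                   rtol=1e-12)
        np.testing.assert_allclose(sm.values.mean(axis=1), 1.0, atol=1e-12)


class TestUnrotatedFactorModel:
    def test_rank_one_exact(self):
        u, v = np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 4.0, 3.0])
        sm = average_scale(ConcentrationMatrix(
            np.outer(u, v), ("a", "b", "c"), ("s1", "s2", "s3", "s4")))
        C0, R0, vf = unrotated_factor_model(sm, 1)
        assert np.linalg.norm(sm.values - C0 @ R0) <= 1e-10
        np.testing.assert_allclose(vf, [1.0], atol=1e-12)

    def test_full_rank_exact(self, noisy_cm):
        sm = average_scale(noisy_cm)
        n = min(noisy_cm.n_compounds, noisy_cm.n_samples)
        C0, R0, vf = unrotated_factor_model(sm, n)
        assert np.linalg.norm(sm.values - C0 @ R0) <= 1e-8
        assert np.all(np.diff(vf) <= 1e-12) and vf.sum() <= 1 + 1e-12

    def test_rank2_residual_equals_svd_tail(self):
        """Independent oracle: residual SS = sum of squared singular values
        beyond the kept pair."""
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(5, 2, (6, 8))) + 0.5
        sm = average_scale(ConcentrationMatrix(
            vals, tuple("abcdef"), tuple(f"s{j}" for j in range(8))))
        C0, R0, _ = unrotated_factor_model(sm, 2)
        s = np.linalg.svd(sm.values, compute_uv=False)
        resid = np.sum((sm.values - C0 @ R0) ** 2)
        np.testing.assert_allclose(resid, np.sum(s[2:] ** 2), rtol=1e-10)

    def test_out_of_range_n(self, toy_cm):
        sm = average_scale(toy_cm)
        with pytest.raises(ValueError):
            unrotated_factor_model(sm, 0)
        with pytest.raises(ValueError):
            unrotated_factor_model(sm, 3)


class TestNncRotate:
    def test_exactly_factorable_converges(self, truth3, noiseless_cm):
        fs = fit_fannc(noiseless_cm, 3)
        assert fs.converged
        assert fs.neg_ss < 1e-4
        assert fs.relative_residual <= 1e-2
        assert np.all(fs.scores >= -1e-8)
        assert np.all(fs.loadings >= 0)

    def test_nonnegative_input_is_fixed_point(self):
        rng = np.random.default_rng(5)
        C = np.abs(rng.normal(1, 0.3, (6, 2)))
        R = np.abs(rng.normal(1, 0.3, (2, 8)))
        D = C @ R
        cm = ConcentrationMatrix(D, tuple(f"c{i}" for i in range(6)),
                                 tuple(f"s{j}" for j in range(8)))
        sm = average_scale(cm)
        Cs = C / sm.row_means[:, None]
        fs = nnc_rotate(Cs, R, sm, refine="none")
        assert fs.converged and fs.iterations <= 3
        np.testing.assert_allclose(reconstruct(fs), D, rtol=1e-8)

    def test_nonconvergence_is_flagged_not_raised(self, noisy_cm):
        sm = average_scale(noisy_cm)
        C0, R0, _ = unrotated_factor_model(sm, 3)
        fs = nnc_rotate(C0, R0, sm, tol=0.0, max_iter=2)
        assert isinstance(fs, FactorSolution)
        assert not fs.converged

    def test_minvol_refine_preserves_reconstruction(self, noiseless_cm):
        raw = fit_fannc(noiseless_cm, 3, refine="none")
        ref = fit_fannc(noiseless_cm, 3, refine="minvol")
        np.testing.assert_allclose(reconstruct(ref), reconstruct(raw),
                                   rtol=1e-4, atol=1e-8)


class TestReconstruct:
    def test_outer_product(self):
        fs = FactorSolution(np.array([[1.0], [2.0]]), np.array([[3.0, 4.0]]),
                            1, 0.0, 1, True, 0.0)
        np.testing.assert_array_equal(reconstruct(fs), [[3, 4], [6, 8]])

    def test_zero_scores_give_zero_matrix(self):
        fs = FactorSolution(np.array([[1.0], [2.0]]), np.zeros((1, 3)),
                            1, 0.0, 1, True, 0.0)
        assert not reconstruct(fs).any()

    def test_noiseless_end_to_end_within_one_percent(self, noiseless_cm):
        fs = fit_fannc(noiseless_cm, 3)
        err = np.linalg.norm(noiseless_cm.values - reconstruct(fs)) \
            / np.linalg.norm(noiseless_cm.values)
        assert err <= 1e-2


class TestNormalizeProfiles:
    def test_column_arithmetic_and_idempotence(self):
        L = np.array([[2.0, 0.2], [3.0, 0.3], [5.0, 0.5]])
        P = normalize_profiles(L)
        np.testing.assert_allclose(P[:, 0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalize_profiles(P), P)

    def test_zero_column_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_profiles(np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_cosine_similarity_invariant_under_normalization(self, noisy_cm):
        from fannc import cosine_similarity
        fs = fit_fannc(noisy_cm, 3)
        P = normalize_profiles(fs)
        for k in range(3):
            assert cosine_similarity(P[:, k], fs.loadings[:, k]) == \
                pytest.approx(1.0, abs=1e-12)


class TestContributions:
    def test_single_factor_is_100_percent(self):
        fs = FactorSolution(np.array([[1.0], [2.0]]), np.array([[3.0, 4.0]]),
                            1, 0.0, 1, True, 0.0, sample_labels=("s1", "s2"))
        ct = contributions(fs)
        np.testing.assert_allclose(ct.per_sample, 100.0)
        np.testing.assert_allclose(ct.overall, [100.0])

    def test_identity_loadings_arithmetic(self):
        fs = FactorSolution(np.eye(2), np.array([[3.0], [1.0]]) * np.ones((2, 2)),
                            2, 0.0, 1, True, 0.0, sample_labels=("s1", "s2"))
        ct = contributions(fs)
        np.testing.assert_allclose(ct.per_sample[:, 0], [75.0, 25.0])

    def test_columns_sum_to_100(self, noisy_cm):
        ct = contributions(fit_fannc(noisy_cm, 3))
        np.testing.assert_allclose(ct.per_sample.sum(axis=0), 100.0, atol=1e-6)
        assert np.all(ct.per_sample >= 0) and np.all(ct.per_sample <= 100 + 1e-9)

    def test_weighted_and_unweighted_both_reported(self, noisy_cm):
        ct = contributions(fit_fannc(noisy_cm, 3), weighting="weighted")
        np.testing.assert_allclose(ct.overall, ct.overall_weighted)
        np.testing.assert_allclose(ct.overall.sum(), 100.0, atol=1e-9)
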