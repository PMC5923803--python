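"""Cell perturbation, factor alignment and the uncertainty ensemble."""

import itertools

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

from fannc import (
    ConcentrationMatrix, align_factors, fit_fannc, generate_truth,
    perturb_concentrations, run_uncertainty_ensemble, synthesize_dataset,
)
from fannc.core import FactorSolution


class _FixedUniform:
    """Stub generator returning a constant uniform draw."""

    def __init__(self, u):
        self.u = u

    def random(self, shape):
        return np.full(shape, self.u)


class TestPerturbConcentrations:
    def test_median_draw_returns_input_exactly(self, noisy_cm):
        out = perturb_concentrations(noisy_cm, 0.2, _FixedUniform(0.5))
        np.testing.assert_array_equal(out.values, noisy_cm.values)

    def test_zero_cv_returns_input_for_any_draw(self, noisy_cm):
        rng = np.random.default_rng(3)
        out = perturb_concentrations(noisy_cm, 0.0, rng)
        np.testing.assert_array_equal(out.values, noisy_cm.values)

    def test_bracket_matches_independent_inverse_erf(self):
        """Oracle: invert the error function with a root-finder instead of
        scipy's erfinv, then check the perturbed cell value."""
        u = 0.841345
        z = brentq(lambda x: erf(x) - (2 * u - 1), -6, 6)
        expected = 10.0 + 0.1 * 10.0 * 2.0 * z
        cm = ConcentrationMatrix(np.full((2, 2), 10.0), ("a", "b"), ("s1", "s2"))
        out = perturb_concentrations(cm, 0.1, _FixedUniform(u))
        np.testing.assert_allclose(out.values, expected, rtol=1e-6)
        assert out.values[0, 0] == pytest.approx(11.41421, abs=1e-4)

    def test_unit_sd_convention_scales_bracket_by_inv_sqrt2(self, noisy_cm):
        u = 0.9
        printed = perturb_concentrations(noisy_cm, 0.1, _FixedUniform(u))
        unit = perturb_concentrations(noisy_cm, 0.1, _FixedUniform(u),
                                      convention="unit_sd")
        dev_p = printed.values / noisy_cm.values - 1
        dev_u = unit.values / noisy_cm.values - 1
        np.testing.assert_allclose(dev_p, dev_u * np.sqrt(2), rtol=1e-12)

    def test_negative_cv_rejected(self, noisy_cm):
        with pytest.raises(ValueError):
            perturb_concentrations(noisy_cm, -0.1, np.random.default_rng(0))

    def test_high_cv_output_stays_non_negative(self, noisy_cm):
        rng = np.random.default_rng(7)
        out = perturb_concentrations(noisy_cm, 2.5, rng)
        assert np.all(out.values >= 0)


class TestAlignFactors:
    def _solution(self, loadings, scores):
        return FactorSolution(loadings, scores, loadings.shape[1],
                              0.0, 1, True, 0.0)

    def test_swap_is_undone(self, truth3):
        ref = self._solution(truth3.true_profiles, truth3.true_scores)
        perm = [2, 0, 1]
        cand = self._solution(truth3.true_profiles[:, perm],
                              truth3.true_scores[perm, :])
        out = align_factors(cand, ref)
        np.testing.assert_allclose(out.loadings, ref.loadings)
        np.testing.assert_allclose(out.scores, ref.scores)

    def test_identity_permutation(self, truth3):
        ref = self._solution(truth3.true_profiles, truth3.true_scores)
        out = align_factors(ref, ref)
        np.testing.assert_array_equal(out.loadings, ref.loadings)

    def test_matches_brute_force_over_permutations(self):
        from fannc import cosine_similarity
        rng = np.random.default_rng(17)
        for trial in range(5):
            A = rng.random((10, 3)) + 0.05
            B = rng.random((10, 3)) + 0.05
            ref, cand = self._solution(A, rng.random((3, 6))), \
                self._solution(B, rng.random((3, 6)))
            out = align_factors(cand, ref)
            got = sum(cosine_similarity(out.loadings[:, k], A[:, k])
                      for k in range(3))
            best = max(
                sum(cosine_similarity(B[:, p[k]], A[:, k]) for k in range(3))
                for p in itertools.permutations(range(3)))
            assert got == pytest.approx(best, abs=1e-12)

    def test_dimension_mismatch_errors(self, truth3):
        ref = self._solution(truth3.true_profiles, truth3.true_scores)
        cand = self._solution(truth3.true_profiles[:, :2],
                              truth3.true_scores[:2, :])
        with pytest.raises(ValueError):
            align_factors(cand, ref)


class TestUncertaintyEnsemble:
    def test_zero_cv_gives_exactly_zero_sd(self, noisy_cm):
        ens = run_uncertainty_ensemble(noisy_cm, 3, cv=0.0, n_runs=5, seed=2)
        assert ens.n_converged == 5
        np.testing.assert_array_equal(ens.profile_sd, 0.0)
        np.testing.assert_array_equal(ens.contribution_per_sample_sd, 0.0)

    def test_same_seed_is_bitwise_reproducible(self, noisy_cm):
        a = run_uncertainty_ensemble(noisy_cm, 3, cv=0.1, n_runs=8, seed=42)
        b = run_uncertainty_ensemble(noisy_cm, 3, cv=0.1, n_runs=8, seed=42)
        np.testing.assert_array_equal(a.profile_mean, b.profile_mean)
        np.testing.assert_array_equal(a.profile_sd, b.profile_sd)
        np.testing.assert_array_equal(a.contribution_overall_mean,
                                      b.contribution_overall_mean)

    def test_extending_runs_preserves_early_replicates(self, noisy_cm):
        short = run_uncertainty_ensemble(noisy_cm, 3, cv=0.1, n_runs=4, seed=9)
        long = run_uncertainty_ensemble(noisy_cm, 3, cv=0.1, n_runs=8, seed=9)
        np.testing.assert_array_equal(short.replicate_profiles,
                                      long.replicate_profiles[:4])

    def test_sd_non_decreasing_in_cv(self):
        """More input noise never shrinks output uncertainty."""
        truth = generate_truth(m=9, n=2, r=12, seed=31, separation=0.9)
        cm = synthesize_dataset(truth, noise_cv=0.0)
        sds = []
        for cv in (0.0, 0.05, 0.1, 0.2):
            ens = run_uncertainty_ensemble(cm, 2, cv=cv, n_runs=30, seed=77)
            sds.append(ens.contribution_overall_sd.mean())
        assert np.all(np.diff(sds) >= -1e-12)

    def test_alignment_makes_summaries_follow_base_order(self, noisy_cm):
        ens = run_uncertainty_ensemble(noisy_cm, 3, cv=0.05, n_runs=6, seed=4)
        base_prof = ens.base_solution.loadings / ens.base_solution.loadings.sum(0)
        # each factor's replicate-mean profile resembles the base factor
        from fannc import cosine_similarity
        for k in range(3):
            assert cosine_similarity(ens.profile_mean[:, k], base_prof[:, k]) > 0.98
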