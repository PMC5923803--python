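"""Monte Carlo uncertainty propagation through the FA-NNC fit.

Each replicate perturbs every cell of the measured matrix ``A`` with
multiplicative noise scaled by a coefficient of variation (CV):

    D_ij = A_ij + cv_ij · A_ij · [2·erfinv(2·U_ij − 1)],   U_ij ~ Uniform(0, 1)

The bracketed term is a zero-mean normal deviate — with standard
deviation √2 under this formula as written, since ``√2·erfinv(2U−1)`` is
the standard-normal quantile of ``U``.  Both conventions are supported
(``convention="printed"`` keeps the √2 factor, ``"unit_sd"`` rescales to
a standard normal); the printed form is the default.  Cells that come
out negative are redrawn, then clamped to zero after a retry cap.

A full FA-NNC fit is run on every perturbed matrix.  Because the factor
order of each replicate is arbitrary, replicates are permutation-aligned
to the base solution by maximizing summed profile cosine similarity
(Hungarian assignment) before per-entry means and standard deviations of
normalized profiles and percent contributions are accumulated.  Only
converged replicates enter the summaries; their count is reported.

Each replicate draws from its own child stream of the master seed, so
increasing ``n_runs`` extends the ensemble without reshuffling earlier
replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import erfinv

from .core import FactorSolution, contributions, fit_fannc, normalize_profiles
from .io import ConcentrationMatrix
from .matching import cosine_similarity

logger = logging.getLogger("fannc")

#: redraw a negative perturbed cell at most this many times before clamping
NEGATIVE_REDRAW_CAP = 100


@dataclass(frozen=True)
class UncertaintyEnsemble:
    """Aligned replicate solutions and their mean/SD summaries."""

    base_solution: FactorSolution
    replicate_profiles: np.ndarray          # (n_converged, m, n)
    replicate_contributions: np.ndarray     # (n_converged, n, r) percent
    profile_mean: np.ndarray                # (m, n)
    profile_sd: np.ndarray                  # (m, n)
    contribution_per_sample_mean: np.ndarray  # (n, r)
    contribution_per_sample_sd: np.ndarray    # (n, r)
    contribution_overall_mean: np.ndarray     # (n,)
    contribution_overall_sd: np.ndarray       # (n,)
    n_runs: int
    n_converged: int
    seed: int
    n_clamped_cells: int


def perturb_concentrations(A: ConcentrationMatrix, cv, rng: np.random.Generator,
                           convention: str = "printed") -> ConcentrationMatrix:
    """Draw one noise replicate of the concentration matrix.

    ``cv`` may be a scalar, a per-compound vector of length m, or a full
    m × r matrix.  Negative results are redrawn cell-wise up to
    :data:`NEGATIVE_REDRAW_CAP` times, then clamped to 0 with a logged
    count, preserving the non-negativity invariant without biasing
    low-CV runs.
    """
    if convention not in ("printed", "unit_sd"):
        raise ValueError("convention must be 'printed' or 'unit_sd'")
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be ≥ 0")
    if cv.ndim == 1:
        cv = cv[:, None]
    scale = 2.0 if convention == "printed" else np.sqrt(2.0)

    def draw(shape):
        u = rng.random(shape)
        return scale * erfinv(2.0 * u - 1.0)

    vals = A.values * (1.0 + cv * draw(A.values.shape))
    clamped = 0
    for _ in range(NEGATIVE_REDRAW_CAP):
        neg = vals < 0
        if not neg.any():
            break
        redraw = A.values * (1.0 + cv * draw(A.values.shape))
        vals = np.where(neg, redraw, vals)
    neg = vals < 0
    if neg.any():
        clamped = int(neg.sum())
        logger.warning("clamped %d negative perturbed cells to 0", clamped)
        vals = np.where(neg, 0.0, vals)
    cm = ConcentrationMatrix(vals, A.compound_labels, A.sample_labels, A.units)
    object.__setattr__(cm, "_n_clamped", clamped)
    return cm


def align_factors(candidate: FactorSolution, reference: FactorSolution) -> FactorSolution:
    """Permute a replicate's factors to match a reference solution.

    The permutation maximizes the summed cosine similarity between
    matched normalized profiles (solved exactly by linear-sum
    assignment); scores are permuted consistently.
    """
    if candidate.n_factors != reference.n_factors:
        raise ValueError("factor-count mismatch")
    if candidate.loadings.shape[0] != reference.loadings.shape[0]:
        raise ValueError("compound-axis mismatch")
    n = candidate.n_factors
    sim = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            sim[i, j] = cosine_similarity(reference.loadings[:, i],
                                          candidate.loadings[:, j])
    _, perm = linear_sum_assignment(-sim)
    if np.array_equal(perm, np.arange(n)):
        return candidate
    return FactorSolution(
        loadings=candidate.loadings[:, perm],
        scores=candidate.scores[perm, :],
        n_factors=n,
        neg_ss=candidate.neg_ss,
        iterations=candidate.iterations,
        converged=candidate.converged,
        relative_residual=candidate.relative_residual,
        clamped_mass=candidate.clamped_mass,
        compound_labels=candidate.compound_labels,
        sample_labels=candidate.sample_labels,
    )


def run_uncertainty_ensemble(A: ConcentrationMatrix, n_factors: int, cv,
                             n_runs: int = 1000, seed: int = 0,
                             tol: float = 1e-4, max_iter: int = 500,
                             convention: str = "printed",
                             weighting: str = "unweighted") -> UncertaintyEnsemble:
    """Propagate CV noise through ``n_runs`` full FA-NNC fits.

    Raises if the base fit on the unperturbed matrix does not converge,
    or if more than half the replicates fail to converge.  Summaries are
    per-entry means and standard deviations (population SD, ddof=0) over
    the converged, aligned replicates and are fully reproducible from
    ``seed``.
    """
    base = fit_fannc(A, n_factors, tol=tol, max_iter=max_iter)
    if not base.converged:
        raise RuntimeError(
            f"base FA-NNC fit did not converge (neg_ss={base.neg_ss:.3e})")

    streams = np.random.SeedSequence(seed).spawn(n_runs)
    profiles, contribs = [], []
    n_clamped = 0
    for run, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pert = perturb_concentrations(A, cv, rng, convention=convention)
        n_clamped += getattr(pert, "_n_clamped", 0)
        fit = fit_fannc(pert, n_factors, tol=tol, max_iter=max_iter)
        if not fit.converged:
            logger.info("replicate %d did not converge (neg_ss=%.3e); excluded",
                        run, fit.neg_ss)
            continue
        fit = align_factors(fit, base)
        profiles.append(normalize_profiles(fit))
        contribs.append(contributions(fit, weighting=weighting).per_sample)

    n_conv = len(profiles)
    if n_runs and n_conv < 0.5 * n_runs:
        raise RuntimeError(
            f"only {n_conv}/{n_runs} Monte Carlo replicates converged; "
            f"the factorization is unstable at this factor count/CV")

    P = np.asarray(profiles)   # (n_conv, m, n)
    K = np.asarray(contribs)   # (n_conv, n, r)
    overall = K.mean(axis=2)   # per-replicate overall percents (n_conv, n)
    if np.all(np.asarray(cv) == 0):
        # replicates are bit-identical; report exact zeros rather than the
        # ~1-ulp artifacts of averaging n identical floats
        return UncertaintyEnsemble(
            base_solution=base,
            replicate_profiles=P,
            replicate_contributions=K,
            profile_mean=P[0].copy(),
            profile_sd=np.zeros_like(P[0]),
            contribution_per_sample_mean=K[0].copy(),
            contribution_per_sample_sd=np.zeros_like(K[0]),
            contribution_overall_mean=overall[0].copy(),
            contribution_overall_sd=np.zeros(overall.shape[1]),
            n_runs=n_runs,
            n_converged=n_conv,
            seed=seed,
            n_clamped_cells=n_clamped,
        )
    return UncertaintyEnsemble(
        base_solution=base,
        replicate_profiles=P,
        replicate_contributions=K,
        profile_mean=P.mean(axis=0),
        profile_sd=P.std(axis=0),
        contribution_per_sample_mean=K.mean(axis=0),
        contribution_per_sample_sd=K.std(axis=0),
        contribution_overall_mean=overall.mean(axis=0),
        contribution_overall_sd=overall.std(axis=0),
        n_runs=n_runs,
        n_converged=n_conv,
        seed=seed,
        n_clamped_cells=n_clamped,
    )
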